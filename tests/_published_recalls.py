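"""Published per-class recall rows (%) for seven classifiers on a nine-class
seed-cotton foreign-fiber benchmark (plastic film, seed cotton, paper scraps,
black film, white/red/transparent rope, foam board, tray background).

Used as fixtures for the metric-aggregation algebra: the benchmark's AA
column must equal the mean of each row to the printed 4 decimals.
"""

# model name -> (per-class recalls, published AA)
PUBLISHED_RECALLS = {
    "svm": (
        [86.8235, 98.0455, 98.6301, 98.3645, 95.2278, 96.7608, 84.9696, 97.0863, 98.8814],
        94.9766,
    ),
    "resnet18": (
        [96.1599, 97.3134, 97.4137, 97.2909, 96.3791, 96.6651, 94.261, 96.9235, 97.4283],
        96.6483,
    ),
    "cnn2d": (
        [95.8156, 97.2287, 97.5728, 97.3524, 96.4459, 96.3619, 93.6848, 96.9339, 97.4663],
        96.5403,
    ),
    "fast3dcnn": (
        [92.458, 96.783, 97.334, 96.992, 96.613, 96.761, 90.949, 96.276, 97.174],
        95.7043,
    ),
    "hresnet": (
        [96.2931, 97.2018, 97.5367, 97.1944, 96.5627, 95.6119, 94.3426, 97.1903, 97.4518],
        96.5984,
    ),
    "spectralformer": (
        [97.6044, 98.7398, 98.7538, 98.8123, 97.3135, 97.6703, 95.3362, 96.3519, 98.6456],
        97.692,
    ),
    "mjhresnet": (
        [98.386, 99.296, 99.449, 99.581, 98.265, 98.5, 96.107, 99.453, 99.373],
        98.7122,
    ),
}
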