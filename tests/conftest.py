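import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def oracle_dilate(plane: np.ndarray, radius: int, metric: str = "euclidean") -> np.ndarray:
    """Independent per-pixel flat dilation: max over in-image footprint.

    Deliberately different route from the implementation: pads with -inf
    and loops over pixels.
    """
    return _oracle_morph(plane, radius, metric, np.max, -np.inf)


def oracle_erode(plane: np.ndarray, radius: int, metric: str = "euclidean") -> np.ndarray:
    return _oracle_morph(plane, radius, metric, np.min, np.inf)


def _oracle_morph(plane, radius, metric, reducer, pad_value):
    plane = np.asarray(plane, dtype=np.float64)
    r = radius
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    if metric == "euclidean":
        fp = dy**2 + dx**2 <= r**2
    elif metric == "manhattan":
        fp = np.abs(dy) + np.abs(dx) <= r
    else:
        fp = np.maximum(np.abs(dy), np.abs(dx)) <= r
    padded = np.pad(plane, r, constant_values=pad_value)
    H, W = plane.shape
    out = np.empty_like(plane)
    for y in range(H):
        for x in range(W):
            window = padded[y : y + 2 * r + 1, x : x + 2 * r + 1]
            out[y, x] = reducer(window[fp])
    return out.astype(np.int64)


def oracle_close(plane: np.ndarray, radius: int, metric: str = "euclidean") -> np.ndarray:
    return oracle_erode(oracle_dilate(plane, radius, metric), radius, metric)


def oracle_auc(scores, truths) -> float:
    """Mann-Whitney concordant-pair AUC; ties count half."""
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths)
    pos = scores[truths == 1]
    neg = scores[truths == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
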