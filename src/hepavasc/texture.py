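"""In-plane RMS texture mapping and healthy/metastatic tissue classification.

The roughness of the parenchyma is estimated per CT slice as the RMS of the
grey values in a square sliding window after subtracting the window mean
(equivalently, the population standard deviation of the window's valid
pixels).  Vessel/nodule/artefact pixels are excluded.  Tissue is then
classified by the band rule: a window is healthy or metastatic when its RMS
falls within the class mean ± 1.5 standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .volume import Volume3D

__all__ = [
    "RMSMap",
    "ClassStats",
    "TissueClassMap",
    "rms_map",
    "class_stats",
    "classify_tissue",
    "class_fractions",
    "LABELS",
]

BAND_K = 1.5               # class band half-width in standard deviations
MIN_VALID_FRACTION = 0.10  # windows with fewer valid pixels are undefined

LABELS = {"healthy": 0, "metastatic": 1, "unclassified": 2, "excluded": 3}
_LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class RMSMap:
    """Per-slice grid of window RMS values; NaN where undefined."""

    values: np.ndarray        # (nz, ny_w, nx_w)
    window_side: int
    stride: int
    voxel_size: float

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def finite_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass(frozen=True)
class ClassStats:
    """Mean/SD of the RMS distribution of one tissue class."""

    label: str
    mean: float
    sd: float
    k: float = BAND_K

    @property
    def band(self) -> tuple[float, float]:
        return (self.mean - self.k * self.sd, self.mean + self.k * self.sd)

    def contains(self, value: float) -> bool:
        lo, hi = self.band
        return lo <= value <= hi


@dataclass
class TissueClassMap:
    """Per-window tissue labels (see :data:`LABELS`)."""

    labels: np.ndarray  # int8, same grid as the RMSMap
    window_side: int
    stride: int


def _window_sums(a: np.ndarray, w: int, stride: int) -> np.ndarray:
    """Sums of ``a`` over w×w windows at the given stride (valid positions)."""
    # integral image with a leading zero row/column
    ii = np.zeros((a.shape[0] + 1, a.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=ii[1:, 1:])
    ys = np.arange(0, a.shape[0] - w + 1, stride)
    xs = np.arange(0, a.shape[1] - w + 1, stride)
    return (ii[np.ix_(ys + w, xs + w)] - ii[np.ix_(ys, xs + w)]
            - ii[np.ix_(ys + w, xs)] + ii[np.ix_(ys, xs)])


def rms_map(vol: Volume3D, exclusion: np.ndarray | None = None,
            window_side: int = 30, stride: int | None = None) -> RMSMap:
    """In-plane RMS of mean-subtracted grey values per sliding window.

    ``exclusion`` flags pixels (vessels, nodules, artefacts) left out of the
    calculation.  The default stride equals the window side (non-overlapping
    tiles), which leaves the class statistics unchanged in expectation and
    is far cheaper than a dense sliding evaluation; pass ``stride=1`` for
    the dense map.
    """
    if window_side < 2:
        raise ValueError("window_side must be >= 2 pixels")
    nz, ny, nx = vol.shape
    if window_side > ny or window_side > nx:
        raise ValueError(f"window of {window_side} px exceeds slice shape {(ny, nx)}")
    stride = window_side if stride is None else int(stride)
    if exclusion is not None and exclusion.shape != vol.shape:
        raise ValueError("exclusion mask shape mismatch")

    w2 = window_side * window_side
    min_valid = MIN_VALID_FRACTION * w2
    out = []
    for z in range(nz):
        g = np.asarray(vol.data[z], dtype=np.float64)
        valid = np.ones_like(g) if exclusion is None else (~exclusion[z]).astype(np.float64)
        n = _window_sums(valid, window_side, stride)
        s1 = _window_sums(g * valid, window_side, stride)
        s2 = _window_sums(g * g * valid, window_side, stride)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / n
            var = s2 / n - mean ** 2
            rms = np.sqrt(np.maximum(var, 0.0))
        rms[n < min_valid] = np.nan
        out.append(rms)
    return RMSMap(values=np.stack(out), window_side=window_side, stride=stride,
                  voxel_size=vol.voxel_size)


def class_stats(samples: Mapping[str, np.ndarray], k: float = BAND_K,
                min_samples: int = 30) -> dict[str, ClassStats]:
    """Mean/SD of pooled training RMS values per tissue class.

    ``samples`` maps a class label to the RMS values collected from its
    training regions (intact, artefact-free areas).  Classes with fewer than
    ``min_samples`` finite values are rejected.
    """
    stats = {}
    for label, values in samples.items():
        v = np.asarray(values, dtype=float).ravel()
        v = v[np.isfinite(v)]
        if v.size < min_samples:
            raise ValueError(
                f"class {label!r} has only {v.size} valid RMS samples "
                f"(need >= {min_samples})"
            )
        stats[label] = ClassStats(label=label, mean=float(v.mean()),
                                  sd=float(v.std()), k=k)
    return stats


def classify_tissue(rms: RMSMap, stats: Mapping[str, ClassStats]) -> TissueClassMap:
    """Assign each window to healthy/metastatic by the mean ± k·SD band rule.

    A window inside exactly one class band takes that class; inside neither,
    it is unclassified; inside both, the class whose mean is nearer in SD
    units wins (an exact tie stays unclassified).  Undefined windows
    (excluded or data-starved) are marked excluded.
    """
    if set(stats) != {"healthy", "metastatic"}:
        raise ValueError("classification needs exactly the healthy and metastatic classes")
    h, m = stats["healthy"], stats["metastatic"]
    v = rms.values
    labels = np.full(v.shape, LABELS["unclassified"], dtype=np.int8)
    labels[~np.isfinite(v)] = LABELS["excluded"]

    with np.errstate(invalid="ignore"):
        in_h = (v >= h.band[0]) & (v <= h.band[1])
        in_m = (v >= m.band[0]) & (v <= m.band[1])
        zh = np.abs(v - h.mean) / (h.sd if h.sd > 0 else np.inf)
        zm = np.abs(v - m.mean) / (m.sd if m.sd > 0 else np.inf)
        if h.sd == 0:
            zh = np.where(v == h.mean, 0.0, np.inf)
        if m.sd == 0:
            zm = np.where(v == m.mean, 0.0, np.inf)
    only_h = in_h & ~in_m
    only_m = in_m & ~in_h
    both = in_h & in_m
    labels[only_h] = LABELS["healthy"]
    labels[only_m] = LABELS["metastatic"]
    labels[both & (zh < zm)] = LABELS["healthy"]
    labels[both & (zm < zh)] = LABELS["metastatic"]
    # both-band exact tie keeps the unclassified default
    labels[~np.isfinite(v)] = LABELS["excluded"]
    return TissueClassMap(labels=labels, window_side=rms.window_side, stride=rms.stride)


def class_fractions(cls_map: TissueClassMap) -> dict[str, float]:
    """Healthy/metastatic percentages among classified windows (sum 100)."""
    n_h = int((cls_map.labels == LABELS["healthy"]).sum())
    n_m = int((cls_map.labels == LABELS["metastatic"]).sum())
    total = n_h + n_m
    if total == 0:
        raise ValueError("no classified windows")
    return {"healthy": 100.0 * n_h / total, "metastatic": 100.0 * n_m / total}
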