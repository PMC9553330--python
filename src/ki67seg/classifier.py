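"""Ki-67 expression-class prediction from segmentation outputs.

Stage two of the framework: the segmented tumor (plus its 5 mm
peritumoral stromal ring) is summarized as an interpretable radiomic-style
feature vector -- per-region, per-b-value intensity statistics, an
ADC-like log-ratio, and shape descriptors -- which feeds a soft-margin
support vector machine with the polynomial kernel K(x, xi) = (x.xi + 1)^d.

What numeric representation of the segmentation output enters the SVM is
an interpretation of this package: hand-crafted region descriptors were
chosen over flattened masks for dimensional stability and interpretability
(see docs/methods.md).

The quadratic-program fit is delegated to scikit-learn's SVC configured to
this exact kernel; the decision function at predict time is evaluated with
this module's own ``poly_kernel`` against the stored support vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.svm import SVC

from .exceptions import DegenerateInputError, ParameterError
from .roi import RoiSet

__all__ = [
    "Ki67Label",
    "ki67_label_from_index",
    "FeatureVector",
    "extract_features",
    "poly_kernel",
    "SvmModel",
    "fit_svm",
    "predict_svm",
    "cross_validate",
    "KI67_HIGH_CUTOFF_PCT",
]

#: Ki-67 positive-cell fraction at or above which expression is "high".
KI67_HIGH_CUTOFF_PCT = 14.0


@dataclass(frozen=True)
class Ki67Label:
    value: str  # "high" | "low"
    index_pct: float | None = None

    def __post_init__(self) -> None:
        if self.value not in ("high", "low"):
            raise ParameterError(f"unknown Ki-67 class {self.value!r}")
        if self.index_pct is not None:
            expected = "high" if self.index_pct >= KI67_HIGH_CUTOFF_PCT else "low"
            if self.value != expected:
                raise ParameterError(
                    f"label {self.value!r} inconsistent with index {self.index_pct}%"
                )


def ki67_label_from_index(index_pct: float) -> Ki67Label:
    """high iff the Ki-67 positive-cell percentage is >= 14."""
    if not 0 <= index_pct <= 100:
        raise ParameterError("index_pct must be in [0, 100]")
    value = "high" if index_pct >= KI67_HIGH_CUTOFF_PCT else "low"
    return Ki67Label(value=value, index_pct=float(index_pct))


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, np.float64)
        if self.values.ndim != 1 or len(self.values) != len(self.names):
            raise ParameterError("values and names must be 1D and aligned")
        if not np.isfinite(self.values).all():
            raise ParameterError("feature values must be finite")


_STATS = ("mean", "sd", "p10", "p50", "p90")


def _region_stats(pixels: np.ndarray) -> list[float]:
    return [
        float(pixels.mean()),
        float(pixels.std()),
        *(float(v) for v in np.percentile(pixels, (10, 50, 90))),
    ]


def extract_features(images, roi_set: RoiSet, b_values=(0.0, 850.0),
                     spacing: float = 0.7) -> FeatureVector:
    """Per-case descriptor vector from images and the three-ROI geometry.

    Regions x b-values x (mean, sd, p10, p50, p90), an ADC-like mean
    log-ratio ln(S_b0 / S_bmax) / (bmax - b0) over the tumor, a flag for a
    missing stromal ring (whose features then copy the tumor's), and tumor
    shape: area (mm^2), perimeter (mm), circularity 4*pi*A/P^2.
    """
    images = [np.asarray(im, np.float64) for im in images]
    tumor = roi_set.tumor.astype(bool)
    if not tumor.any():
        raise DegenerateInputError("empty tumor ROI")
    ring = roi_set.stroma_ring.astype(bool)
    combined = roi_set.combined.astype(bool)
    ring_missing = not ring.any()

    values: list[float] = []
    names: list[str] = []
    regions = {"tumor": tumor, "ring": tumor if ring_missing else ring,
               "combined": combined}
    for rname, region in regions.items():
        for b, img in zip(b_values, images):
            stats = _region_stats(img[region])
            values.extend(stats)
            names.extend(f"{rname}_b{int(b)}_{s}" for s in _STATS)
    values.append(float(ring_missing))
    names.append("ring_missing")

    # ADC-like feature by inverting the mono-exponential signal model
    b0, bmax = b_values[0], b_values[-1]
    s_low, s_high = images[0][tumor], images[-1][tumor]
    ratio = np.clip(s_low, 1e-6, None) / np.clip(s_high, 1e-6, None)
    values.append(float(np.mean(np.log(np.clip(ratio, 1e-6, None)) / (bmax - b0))))
    names.append("tumor_adc_like")

    area_mm2 = float(tumor.sum()) * spacing**2
    # Crofton estimate approximates the true contour length on a grid
    perimeter_mm = float(measure.perimeter_crofton(tumor, directions=4)) * spacing
    circ = 4 * np.pi * area_mm2 / perimeter_mm**2 if perimeter_mm > 0 else 1.0
    values.extend([area_mm2, perimeter_mm, float(circ)])
    names.extend(["tumor_area_mm2", "tumor_perimeter_mm", "tumor_circularity"])

    return FeatureVector(np.asarray(values), tuple(names))


def poly_kernel(x, xi, d: int = 2):
    """Polynomial kernel (x . xi + 1)^d; symmetric, and K(x, x) >= 1 since
    x.x + 1 >= 1 for any real x.

    Accepts vectors or 2D arrays (rows are samples); returns a scalar or a
    Gram block accordingly.
    """
    if int(d) != d or d < 1:
        raise ParameterError("degree d must be an integer >= 1")
    x = np.asarray(x, np.float64)
    xi = np.asarray(xi, np.float64)
    if x.shape[-1] != xi.shape[-1]:
        raise ParameterError("feature length mismatch")
    if x.ndim == 1 and xi.ndim == 1:
        return float((x @ xi + 1.0) ** int(d))
    return (np.atleast_2d(x) @ np.atleast_2d(xi).T + 1.0) ** int(d)


@dataclass
class SvmModel:
    """Fitted polynomial-kernel SVM in dual form.

    decision(x) = sum_i duals_i * K(sv_i, x~) + bias, with x~ the
    standardized input; the sign convention is +1 = high Ki-67.
    """

    support_vectors: np.ndarray
    duals: np.ndarray
    bias: float
    degree: int
    regularization: float
    feature_names: tuple[str, ...]
    scale_loc: np.ndarray
    scale_sd: np.ndarray
    n_support_by_class: tuple[int, int]  # (low, high)

    def __post_init__(self) -> None:
        if min(self.n_support_by_class) < 1:
            raise ParameterError("need at least one support vector per class")
        if np.abs(self.duals).max() > self.regularization * (1 + 1e-9):
            raise ParameterError("|duals| must be bounded by the regularization C")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, np.float64) - self.scale_loc) / self.scale_sd


def _as_matrix(features) -> np.ndarray:
    rows = [f.values if isinstance(f, FeatureVector) else np.asarray(f, np.float64)
            for f in features]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ParameterError("feature vectors must share one length")
    return np.vstack(rows)


def _as_sign(label) -> int:
    value = label.value if isinstance(label, Ki67Label) else str(label)
    if value not in ("high", "low"):
        raise ParameterError(f"unknown Ki-67 class {value!r}")
    return 1 if value == "high" else -1


def fit_svm(features, labels, degree: int = 2, regularization: float = 1.0
            ) -> SvmModel:
    """Fit the soft-margin dual with kernel (x.xi + 1)^d on standardized
    features; the scaling is stored in the model."""
    x = _as_matrix(features)
    y = np.array([_as_sign(l) for l in labels])
    if len(x) != len(y) or len(x) < 2:
        raise ParameterError("need >= 2 aligned samples")
    if len(np.unique(y)) < 2:
        raise ParameterError("both Ki-67 classes must be present")
    if int(degree) != degree or degree < 1:
        raise ParameterError("degree must be an integer >= 1")

    loc = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - loc) / sd

    svc = SVC(C=regularization, kernel="poly", degree=int(degree),
              gamma=1.0, coef0=1.0)
    svc.fit(xs, y)

    names = (features[0].names if isinstance(features[0], FeatureVector)
             else tuple(f"f{i}" for i in range(x.shape[1])))
    return SvmModel(
        support_vectors=svc.support_vectors_.copy(),
        duals=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        degree=int(degree),
        regularization=float(regularization),
        feature_names=names,
        scale_loc=loc,
        scale_sd=sd,
        n_support_by_class=tuple(int(n) for n in svc.n_support_),
    )


def decision_score(model: SvmModel, features) -> float:
    """Kernel-expansion decision value for one raw feature vector."""
    f = features.values if isinstance(features, FeatureVector) else np.asarray(features)
    if f.shape[-1] != model.support_vectors.shape[1]:
        raise ParameterError("feature length mismatch with the fitted model")
    xs = model.standardize(f)
    k = poly_kernel(model.support_vectors, xs[None, :], model.degree)[:, 0]
    return float(model.duals @ k + model.bias)


def predict_svm(model: SvmModel, features) -> tuple[Ki67Label, float]:
    """Predict high/low Ki-67 for raw (unstandardized) features."""
    score = decision_score(model, features)
    return Ki67Label("high" if score >= 0 else "low"), score


def cross_validate(features, labels, degree: int = 2, regularization: float = 1.0,
                   n_folds: int = 5, seed: int = 0) -> float:
    """Stratified k-fold accuracy of the polynomial-kernel SVM."""
    x = _as_matrix(features)
    y = np.array([_as_sign(l) for l in labels])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCF]))
    folds = np.empty(len(y), int)
    for cls in (-1, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    correct = 0
    for k in range(n_folds):
        test = folds == k
        model = fit_svm(x[~test], ["high" if s > 0 else "low" for s in y[~test]],
                        degree=degree, regularization=regularization)
        preds = np.array([predict_svm(model, row)[1] >= 0 for row in x[test]])
        correct += int((preds == (y[test] > 0)).sum())
    return correct / len(y)
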