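"""Dynamic feature selection (DFS): a per-test-sample cascade of three gates.

For every held-out sample the cascade re-selects EMF features from scratch:

C1 (test-independent): keep feature k iff its Fisher discriminant score
    FDS_k = SB_k / SW_k exceeds a threshold, where SB_k is the squared
    scatter of the two class means about the global mean and SW_k sums the
    per-class mean squared deviations.

C2 (test-dependent): keep k iff the Mahalanobis ratio
    MR_k = M_near^2 / M_far is below a threshold, where M_near and M_far are
    the smaller and larger of the per-feature scalar Mahalanobis distances
    M_k(s, d) = (s_k - mean_dk)^2 / var_dk from the two classes.  Low MR
    means the test element is close to one class while far from the other;
    an outlier to both classes has MR ~ z^2 and an element midway between two
    well-separated classes has MR ~ (separation/2)^2, so both of the cases
    the gate is meant to remove score high.  Anchoring at the *nearer* class
    (rather than fixedly at class 1) keeps the ratio's stated meaning
    symmetric in the classes; the two forms coincide whenever the test
    element is nearer class 1.

C3 (test-dependent): keep k iff the larger of the two fitted Gaussian class
    densities at s_k is high enough — i.e. the test element is plausibly
    drawn from at least one class.  The default threshold is expressed in
    z-units (keep if the nearest class mean is within ``th_p`` class standard
    deviations), which is scale-free; an absolute-density mode is available.

Gates are evaluated in cascade (C2/C3 only on C1 survivors).  Selection is
stateless across test samples: features dropped for one sample are back in
play for the next.  An empty final mask falls back to the C1 mask, then to
all features, so a cross-validation run can never be left without features.

Degenerate conventions (so synthetic corner cases propagate rather than
raise): SW=0 with SB>0 gives FDS=+inf (always kept); a zero-variance class
has distance 0 from its constant and +inf otherwise, and density +inf at the
constant, 0 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emfspeech.emf import EMFDataset

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class DFSThresholds:
    """Cascade thresholds.

    th_fds : float or "pNN" percentile spec resolved against the training
        FDS distribution (default the median, "p50").
    th_mr : upper bound on the Mahalanobis ratio (default 1.0).
    th_p : with ``p_mode="z"`` (default), the z-unit radius around the
        nearest class mean (default 2.5); with ``p_mode="density"``, an
        absolute lower bound on the maximum class density.
    """

    th_fds: float | str = "p50"
    th_mr: float = 1.0
    th_p: float = 2.5
    p_mode: str = "z"

    def __post_init__(self) -> None:
        if isinstance(self.th_fds, str):
            if not (self.th_fds.startswith("p") and self.th_fds[1:].replace(".", "", 1).isdigit()):
                raise ValueError(f"bad percentile spec {self.th_fds!r}")
        if self.th_mr <= 0:
            raise ValueError("th_mr must be > 0")
        if self.th_p < 0:
            raise ValueError("th_p must be >= 0")
        if self.p_mode not in ("z", "density"):
            raise ValueError(f"unknown p_mode {self.p_mode!r}")


@dataclass(frozen=True)
class DFSTrace:
    """Everything the cascade computed for one test sample."""

    fds: np.ndarray
    mr: np.ndarray
    p: np.ndarray
    nearest_z: np.ndarray
    mask_after_c1: np.ndarray
    mask_after_c2: np.ndarray
    mask_after_c3: np.ndarray
    final_mask: np.ndarray
    fallback: str  # "none" | "c1" | "all"
    th_fds_resolved: float
    class_means: np.ndarray = field(default=None)  # (2, n_features)
    class_sds: np.ndarray = field(default=None)  # (2, n_features), unbiased
    class_sizes: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        return {
            "fds": self.fds.tolist(),
            "mr": self.mr.tolist(),
            "p": self.p.tolist(),
            "mask_after_c1": self.mask_after_c1.tolist(),
            "mask_after_c2": self.mask_after_c2.tolist(),
            "mask_after_c3": self.mask_after_c3.tolist(),
            "final_mask": self.final_mask.tolist(),
            "fallback": self.fallback,
            "th_fds_resolved": self.th_fds_resolved,
        }


def _class_split(training: EMFDataset) -> tuple[np.ndarray, np.ndarray]:
    d0 = training.D[training.Y == 0]
    d1 = training.D[training.Y == 1]
    if d0.shape[0] == 0 or d1.shape[0] == 0:
        raise ValueError("training set must contain both classes")
    return d0, d1


def fisher_discriminant_scores(training: EMFDataset) -> np.ndarray:
    """FDS_k = SB_k / SW_k per feature, with the degenerate conventions above."""
    d0, d1 = _class_split(training)
    gm = training.D.mean(axis=0)
    m0, m1 = d0.mean(axis=0), d1.mean(axis=0)
    sb = (m0 - gm) ** 2 + (m1 - gm) ** 2
    sw = np.mean((d0 - m0) ** 2, axis=0) + np.mean((d1 - m1) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fds = np.where(sw > 0, sb / np.where(sw > 0, sw, 1.0), np.where(sb > 0, np.inf, 0.0))
    return fds


def resolve_th_fds(fds: np.ndarray, spec: float | str) -> float:
    """Resolve a "pNN" percentile spec against the training FDS distribution."""
    if isinstance(spec, str):
        q = float(spec[1:])
        finite = fds[np.isfinite(fds)]
        if finite.size == 0:
            return float("inf")
        return float(np.percentile(finite, q))
    return float(spec)


def apply_c1(fds: np.ndarray, th_fds: float | str) -> np.ndarray:
    """C1 gate: strict FDS > threshold."""
    return fds > resolve_th_fds(fds, th_fds)


def _scalar_mahalanobis(s: float, values: np.ndarray) -> float:
    """Squared scalar Mahalanobis distance with unbiased class variance."""
    mean = float(values.mean())
    var = float(values.var(ddof=1))
    if var == 0.0:
        return 0.0 if s == mean else np.inf
    return (s - mean) ** 2 / var


def mahalanobis_ratio(test_value: float, training: EMFDataset, k: int) -> float:
    """MR_k = M_near^2 / M_far for one feature, conventions as above."""
    d0, d1 = _class_split(training)
    if d0.shape[0] < 2 or d1.shape[0] < 2:
        raise ValueError("each class needs >= 2 training values")
    m1 = _scalar_mahalanobis(test_value, d0[:, k])
    m2 = _scalar_mahalanobis(test_value, d1[:, k])
    return _mr_from_distances(m1, m2)


def _mr_from_distances(m1: float, m2: float) -> float:
    near, far = (m1, m2) if m1 <= m2 else (m2, m1)
    if near == 0.0:
        return 0.0  # on a class mean (or a zero-variance constant): keep
    if np.isinf(near):
        return np.inf  # infinitely far from both: remove
    if np.isinf(far):
        return 0.0  # close to one class, infinitely far from the other: keep
    return near * near / far


def max_class_probability(test_value: float, training: EMFDataset, k: int) -> float:
    """Largest of the two fitted Gaussian class densities at the test element."""
    d0, d1 = _class_split(training)
    if d0.shape[0] < 2 or d1.shape[0] < 2:
        raise ValueError("each class needs >= 2 training values")
    return max(
        _gaussian_density(test_value, d0[:, k]),
        _gaussian_density(test_value, d1[:, k]),
    )


def _gaussian_density(s: float, values: np.ndarray) -> float:
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        return np.inf if s == mean else 0.0
    z = (s - mean) / sd
    return float(np.exp(-0.5 * z * z) / (_SQRT_2PI * sd))


def _vector_stats(d0: np.ndarray, d1: np.ndarray):
    means = np.vstack([d0.mean(axis=0), d1.mean(axis=0)])
    sds = np.vstack([d0.std(axis=0, ddof=1), d1.std(axis=0, ddof=1)])
    return means, sds


def _vector_mr(s: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    out = np.empty(s.size)
    var = sds**2
    for k in range(s.size):
        m = []
        for d in (0, 1):
            if var[d, k] == 0.0:
                m.append(0.0 if s[k] == means[d, k] else np.inf)
            else:
                m.append((s[k] - means[d, k]) ** 2 / var[d, k])
        out[k] = _mr_from_distances(m[0], m[1])
    return out


def _vector_density_and_z(
    s: np.ndarray, means: np.ndarray, sds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Max class density and nearest-class z, per feature."""
    p = np.empty(s.size)
    nz = np.empty(s.size)
    for k in range(s.size):
        dens, zs = [], []
        for d in (0, 1):
            if sds[d, k] == 0.0:
                hit = s[k] == means[d, k]
                dens.append(np.inf if hit else 0.0)
                zs.append(0.0 if hit else np.inf)
            else:
                z = (s[k] - means[d, k]) / sds[d, k]
                dens.append(np.exp(-0.5 * z * z) / (_SQRT_2PI * sds[d, k]))
                zs.append(abs(z))
        p[k] = max(dens)
        nz[k] = min(zs)
    return p, nz


def dfs_select(
    training: EMFDataset,
    test_sample: np.ndarray,
    thresholds: DFSThresholds = DFSThresholds(),
) -> tuple[np.ndarray, DFSTrace]:
    """Run the full C1 -> C2 -> C3 cascade for one test sample.

    Returns the final boolean mask over EMF features and a fully populated
    trace.  The mask is guaranteed non-empty via the fallback rule.
    """
    s = np.asarray(test_sample, dtype=float).reshape(-1)
    if s.size != training.D.shape[1]:
        raise ValueError("test vector length does not match training features")
    d0, d1 = _class_split(training)
    fds = fisher_discriminant_scores(training)
    th_resolved = resolve_th_fds(fds, thresholds.th_fds)
    c1 = fds > th_resolved

    means, sds = _vector_stats(d0, d1)
    mr = _vector_mr(s, means, sds)
    p, nearest_z = _vector_density_and_z(s, means, sds)

    c2 = c1 & (mr < thresholds.th_mr)
    if thresholds.p_mode == "z":
        c3_raw = nearest_z <= thresholds.th_p
    else:
        c3_raw = p > thresholds.th_p
    c3 = c2 & c3_raw

    fallback = "none"
    final = c3
    if not final.any():
        final, fallback = c1, "c1"
    if not final.any():
        final, fallback = np.ones_like(c1, dtype=bool), "all"

    trace = DFSTrace(
        fds=fds,
        mr=mr,
        p=p,
        nearest_z=nearest_z,
        mask_after_c1=c1,
        mask_after_c2=c2,
        mask_after_c3=c3,
        final_mask=final,
        fallback=fallback,
        th_fds_resolved=th_resolved,
        class_means=means,
        class_sds=sds,
        class_sizes=(d0.shape[0], d1.shape[0]),
    )
    return final, trace
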