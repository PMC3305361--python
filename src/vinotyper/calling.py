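"""Genotype calling from two-allele hybridization intensities.

The caller works per probe set on samples placed in (contrast, average
intensity) space and proceeds in three stages:

1. A one-, two- and three-component Gaussian mixture is fitted to the
   contrast dimension by EM, with the component count chosen by the
   silhouette score of the hard assignment.  Components are labelled
   AA / AB / BB by the ordering of their contrast centers.
2. Samples with a clearly dominant posterior are assigned; the rest are
   attached by "friends of friends" nearest-neighbour accretion in the
   full 2D space, so gaps between clusters (which the mixture cannot
   see) still separate groups.
3. Each genotype group gets a robust 2D center and scatter (one-step
   Tukey biweight); a sample's confidence is the upper-tail chi-square
   (2 df) probability of its squared Mahalanobis distance, exp(-d^2/2).
   Calls below the confidence threshold become no-calls (N).

Calls are single characters: ``A`` = AA, ``H`` = AB, ``B`` = BB,
``N`` = no-call (``V`` is added later by the VINO stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .transforms import DEFAULT_CCS_K, ccs_transform, ma_transform, summarize_probe_set

__all__ = [
    "CallingParams",
    "MixtureFit",
    "GroupStats",
    "fit_contrast_mixture",
    "silhouette_score",
    "select_component_count",
    "label_components",
    "initial_assignment",
    "friends_of_friends_assign",
    "biweight_location_scale",
    "biweight_group_stats",
    "confidence_scores",
    "call_genotypes",
    "GenotypeCaller",
]

GENOTYPE_CALLS = ("A", "H", "B")
NO_CALL = "N"


@dataclass
class CallingParams:
    """Free constants of the calling stage.

    ab_center_prior : initial contrast center of the AB component for
        the three-component fit (0 is appropriate after CCS).
    confidence_threshold : calls with confidence below this become N.
    het_band : |contrast| below which a lone or two-component cluster
        center is interpreted as AB rather than a homozygote.
    """

    transform: str = "CCS"
    ccs_k: float = DEFAULT_CCS_K
    ab_center_prior: float = 0.0
    confidence_threshold: float = 0.005
    em_tol: float = 1e-6
    em_max_iter: int = 200
    variance_floor: float = 1e-6
    silhouette_k1_threshold: float = 0.6
    het_band: float = 0.25
    biweight_c: float = 5.0
    biweight_eps: float = 1e-4
    distance_scaling: tuple[float, float] | None = None

    def __post_init__(self):
        if not (0 <= self.confidence_threshold < 1):
            raise ValueError("confidence_threshold must be in [0, 1)")
        if self.em_max_iter < 1:
            raise ValueError("em_max_iter must be >= 1")
        if self.transform not in ("MA", "CCS"):
            raise ValueError("transform must be 'MA' or 'CCS'")
        if not (0 < self.silhouette_k1_threshold < 1):
            raise ValueError("silhouette_k1_threshold must be in (0, 1)")


@dataclass
class MixtureFit:
    """A fitted 1D Gaussian mixture in the contrast dimension."""

    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray  # (n_samples, k)
    log_likelihoods: np.ndarray  # trace over EM iterations
    silhouette: float | None = None

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.posteriors, axis=1)


@dataclass
class GroupStats:
    """Robust 2D per-group location/scatter in (contrast, average) space."""

    centers: dict = field(default_factory=dict)  # label -> (2,) array
    scatters: dict = field(default_factory=dict)  # label -> (2, 2) array
    counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# EM mixture in the contrast dimension


def _gaussian_logpdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def fit_contrast_mixture(contrasts, k: int, params: CallingParams | None = None) -> MixtureFit:
    """Fit a k-component (k in 1..3) Gaussian mixture to 1D contrasts by EM.

    Initialization is fixed: for k=3 the component centers start at the
    minimum observed contrast, the AB center prior, and the maximum; for
    k=2 at the minimum and maximum; for k=1 at the mean.  Degenerate
    data (all contrasts equal) forces k=1.
    """
    params = params or CallingParams()
    x = np.asarray(contrasts, dtype=float)
    if x.ndim != 1 or x.size < k:
        raise ValueError(f"need at least k={k} finite contrasts")
    floor = params.variance_floor

    if np.ptp(x) == 0 and k > 1:
        warnings.warn("all contrasts identical; forcing k=1")
        k = 1

    if k == 1:
        means = np.array([x.mean()])
    elif k == 2:
        means = np.array([x.min(), x.max()])
    elif k == 3:
        means = np.array([x.min(), params.ab_center_prior, x.max()])
    else:
        raise ValueError("k must be 1, 2 or 3")

    variances = np.full(k, max(x.var(), floor))
    weights = np.full(k, 1.0 / k)

    ll_trace = []
    log_resp = None
    for _ in range(params.em_max_iter):
        # E-step
        log_joint = _gaussian_logpdf(x[:, None], means[None, :], variances[None, :]) + np.log(weights)[None, :]
        log_norm = np.logaddexp.reduce(log_joint, axis=1)
        ll = float(log_norm.sum())
        log_resp = log_joint - log_norm[:, None]
        resp = np.exp(log_resp)
        ll_trace.append(ll)
        if len(ll_trace) > 1 and abs(ll_trace[-1] - ll_trace[-2]) < params.em_tol:
            break
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = np.maximum((resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk, floor)
        weights = nk / nk.sum()

    return MixtureFit(
        k=k,
        means=means,
        variances=variances,
        weights=weights,
        posteriors=np.exp(log_resp),
        log_likelihoods=np.asarray(ll_trace),
    )


def silhouette_score(points, labels) -> float:
    """Mean silhouette of a hard clustering; singleton clusters score 0.

    For each point, a = mean distance to its own cluster, b = smallest
    mean distance to another cluster, s = (b - a)/max(a, b) (0 when
    a = b = 0).  Requires at least two clusters, each non-empty.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    return float(np.mean(silhouette_samples(pts, labels)))


def select_component_count(contrasts, params: CallingParams | None = None) -> MixtureFit:
    """Fit k=1,2,3 mixtures and pick k by the hard-assignment silhouette.

    The k in {2, 3} with the larger silhouette wins; if the best
    silhouette falls below ``silhouette_k1_threshold`` (or no multi-
    component fit yields two occupied clusters) a single component is
    returned.
    """
    params = params or CallingParams()
    x = np.asarray(contrasts, dtype=float)
    fits = {}
    for k in (1, 2, 3):
        if x.size >= k and (k == 1 or np.ptp(x) > 0):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[k] = fit_contrast_mixture(x, k, params)

    best_k, best_sil = 1, -np.inf
    for k in (2, 3):
        fit = fits.get(k)
        if fit is None or fit.k != k:
            continue
        labels = fit.hard_labels()
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_score(x, labels)
        fit.silhouette = sil
        if sil > best_sil:
            best_k, best_sil = k, sil
    if best_k == 1 or best_sil < params.silhouette_k1_threshold:
        chosen = fits[1]
        chosen.silhouette = best_sil if np.isfinite(best_sil) else None
        return chosen
    return fits[best_k]


def label_components(fit: MixtureFit, params: CallingParams | None = None) -> list[str]:
    """Map mixture components to genotype labels by their contrast centers.

    k=3: highest mean -> AA, lowest -> BB, middle -> AB.  k=2 and k=1
    use the center sign and the configured het band: a center >= band
    is AA, <= -band is BB, otherwise AB (ties resolved toward treating
    the higher component as AA).
    """
    params = params or CallingParams()
    order = np.argsort(fit.means)  # ascending
    labels = [""] * fit.k
    if fit.k == 3:
        labels[order[0]], labels[order[1]], labels[order[2]] = "B", "H", "A"
    elif fit.k == 2:
        lo, hi = fit.means[order[0]], fit.means[order[1]]
        lo_lab = "B" if lo <= -params.het_band else "H"
        hi_lab = "A" if hi >= params.het_band else "H"
        if lo_lab == hi_lab == "H":
            hi_lab = "A"
        labels[order[0]], labels[order[1]] = lo_lab, hi_lab
    else:
        m = fit.means[0]
        labels[0] = "A" if m >= params.het_band else ("B" if m <= -params.het_band else "H")
    return labels


def initial_assignment(fit: MixtureFit, params: CallingParams | None = None) -> np.ndarray:
    """Assign samples whose posterior clears a per-group median threshold.

    For each component, the "confident" samples are those whose highest
    posterior for any *other* component is below 0.5; the component's
    threshold is the median of the confident samples' posteriors for it
    (0.5 when no sample is confident).  A sample is assigned to a
    component only where its posterior reaches that threshold (>=, so
    saturated posteriors of exactly 1 still assign); remaining samples
    are left unassigned (-1).
    """
    params = params or CallingParams()
    post = fit.posteriors
    n, k = post.shape
    assignment = np.full(n, -1, dtype=int)
    thresholds = np.empty(k)
    for j in range(k):
        others = np.delete(post, j, axis=1)
        confident = others.max(axis=1) < 0.5 if k > 1 else np.ones(n, bool)
        if confident.any():
            thresholds[j] = np.median(post[confident, j])
        else:
            warnings.warn(f"component {j}: no confident samples; threshold falls back to 0.5")
            thresholds[j] = 0.5
    # a sample may clear several thresholds; it goes to its argmax posterior.
    # >= rather than >: posteriors saturate to exactly 1.0 in well-separated
    # clusters, and a whole cluster at the median must still be assigned.
    for i in range(n):
        j = int(np.argmax(post[i]))
        if post[i, j] >= thresholds[j]:
            assignment[i] = j
    return assignment


def friends_of_friends_assign(points, assignment, scales=None) -> np.ndarray:
    """Attach unassigned points to clusters by nearest-neighbour accretion.

    Repeatedly the unassigned point with the smallest (scaled Euclidean)
    distance to *any* assigned point joins that point's group.  Each
    dimension is standardized by its across-sample SD unless explicit
    ``scales`` are given.  Ties break toward the lowest unassigned
    index, then the lowest assigned index.  Exactly one accretion per
    unassigned point; requires at least one assigned point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(assignment).copy()
    if not (labels != -1).any():
        raise ValueError("friends-of-friends requires at least one assigned sample")
    if scales is None:
        scales = pts.std(axis=0)
    scales = np.where(np.asarray(scales, dtype=float) > 0, scales, 1.0)
    z = pts / scales

    while (labels == -1).any():
        un = np.flatnonzero(labels == -1)
        asg = np.flatnonzero(labels != -1)
        d = np.linalg.norm(z[un][:, None, :] - z[asg][None, :, :], axis=2)
        flat = int(np.argmin(d))  # row-major argmin: lowest unassigned, then assigned index
        i, j = np.unravel_index(flat, d.shape)
        labels[un[i]] = labels[asg[j]]
    return labels


# ---------------------------------------------------------------------------
# Robust group statistics and confidence


def _biweight_u(x, c, eps):
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return med, (x - med) / (c * mad + eps)


def biweight_location_scale(values, c: float = 5.0, eps: float = 1e-4):
    """One-step Tukey biweight location and scale around the median.

    u_i = (x_i - median) / (c * MAD + eps); points with |u_i| >= 1 are
    rejected.  Location is the (1 - u^2)^2-weighted mean; the scale is
    the biweight midvariance, whose normalization makes it consistent
    for the SD of uncontaminated Gaussian data:

        s^2 = n * sum (x - M)^2 (1 - u^2)^4 / (sum (1 - u^2)(1 - 5u^2))^2
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one value")
    med, u = _biweight_u(x, c, eps)
    keep = np.abs(u) < 1
    if not keep.any():  # pathological: everything rejected; fall back to median
        return float(med), 0.0
    w = (1 - u[keep] ** 2) ** 2
    loc = float(np.sum(w * x[keep]) / w.sum())
    num = len(x) * np.sum((x[keep] - med) ** 2 * (1 - u[keep] ** 2) ** 4)
    den = np.sum((1 - u[keep] ** 2) * (1 - 5 * u[keep] ** 2)) ** 2
    scale = float(np.sqrt(num / den)) if den > 0 else 0.0
    return loc, scale


def biweight_group_stats(points, c: float = 5.0, eps: float = 1e-4):
    """2D biweight center and scatter (biweight midcovariance matrix).

    Off-diagonal entries follow the midcovariance construction: the
    product of per-dimension (1 - u^2)^2-weighted deviations about the
    medians, normalized by the per-dimension (1 - u^2)(1 - 5u^2) sums,
    which reduces to the midvariance on the diagonal.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    locs = np.empty(2)
    us = []
    for d in range(2):
        loc, _ = biweight_location_scale(pts[:, d], c, eps)
        locs[d] = loc
        us.append(_biweight_u(pts[:, d], c, eps))
    scatter = np.empty((2, 2))
    for p in range(2):
        for q in range(p, 2):
            (mp, up), (mq, uq) = us[p], us[q]
            kp, kq = np.abs(up) < 1, np.abs(uq) < 1
            a = np.where(kp, (pts[:, p] - mp) * (1 - up**2) ** 2, 0.0)
            b = np.where(kq, (pts[:, q] - mq) * (1 - uq**2) ** 2, 0.0)
            dp = np.sum(np.where(kp, (1 - up**2) * (1 - 5 * up**2), 0.0))
            dq = np.sum(np.where(kq, (1 - uq**2) * (1 - 5 * uq**2), 0.0))
            cov = n * np.sum(a * b) / (dp * dq) if dp * dq > 0 else 0.0
            scatter[p, q] = scatter[q, p] = cov
    return locs, scatter


def _floored_scatter(scatter, floor=1e-8):
    s = np.array(scatter, dtype=float)
    s[0, 0] = max(s[0, 0], floor)
    s[1, 1] = max(s[1, 1], floor)
    if np.linalg.det(s) <= 0:  # singular: drop the covariance term
        s = np.diag(np.diag(s))
        s[0, 0] = max(s[0, 0], floor)
        s[1, 1] = max(s[1, 1], floor)
    return s


def compute_group_stats(points, labels, params: CallingParams | None = None) -> GroupStats:
    """Biweight 2D center/scatter per genotype group.

    Groups with fewer than 3 members fall back to their plain mean and a
    diagonal scatter scaled from the across-sample variance.  Each
    group's per-dimension variance is floored at a quarter of the
    size-weighted pooled within-group variance: biweight scale
    estimates from small groups occasionally collapse, and an
    implausibly tight group would otherwise flag ordinary samples as
    extreme.
    """
    params = params or CallingParams()
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels)
    global_var = np.maximum(pts.var(axis=0), 1e-8)
    stats = GroupStats()
    for lab in np.unique(labels):
        if lab == NO_CALL or lab == -1:
            continue
        members = pts[labels == lab]
        if len(members) >= 3:
            loc, scatter = biweight_group_stats(members, params.biweight_c, params.biweight_eps)
        else:
            loc = members.mean(axis=0)
            scatter = np.diag(global_var)
        stats.centers[lab] = loc
        stats.scatters[lab] = _floored_scatter(scatter)
        stats.counts[lab] = int(len(members))
    if stats.counts:
        total = sum(stats.counts.values())
        pooled = sum(stats.counts[lab] * np.diag(stats.scatters[lab]) for lab in stats.counts) / total
        floor = pooled / 4.0
        for lab, scatter in stats.scatters.items():
            s = scatter.copy()
            rescale = np.sqrt(np.maximum(floor / np.maximum(np.diag(s), 1e-300), 1.0))
            s = s * rescale[:, None] * rescale[None, :]  # keeps correlation, lifts SDs
            stats.scatters[lab] = _floored_scatter(s)
    return stats


def confidence_scores(points, labels, group_stats: GroupStats, params: CallingParams | None = None):
    """Chi-square (2 df) upper-tail confidence of each sample in its group.

    confidence = exp(-d^2 / 2) where d is the Mahalanobis distance to
    the group's robust center.  Samples below the confidence threshold
    are returned as no-calls.

    Returns ``(calls, confidence)`` where calls is the label array with
    below-threshold entries replaced by N.
    """
    params = params or CallingParams()
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=object)
    conf = np.ones(len(pts))
    calls = labels.copy()
    for lab, center in group_stats.centers.items():
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            continue
        inv = np.linalg.inv(group_stats.scatters[lab])
        diff = pts[idx] - center
        d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        conf[idx] = np.exp(-d2 / 2.0)
    below = conf < params.confidence_threshold
    calls[below] = NO_CALL
    return calls, conf


# ---------------------------------------------------------------------------
# Per-probe orchestration


@dataclass
class ProbeCallResult:
    calls: np.ndarray  # object array of single-char calls
    confidence: np.ndarray
    points: np.ndarray  # (n, 2) transformed coordinates
    fit: MixtureFit
    group_stats: GroupStats
    pre_n_labels: np.ndarray  # genotype labels before the confidence stage


def call_probe(a, b, params: CallingParams | None = None) -> ProbeCallResult:
    """Run the full calling pipeline for one probe set.

    ``a`` and ``b`` are per-sample linear allele intensities (already
    strand-summarized and normalized).
    """
    params = params or CallingParams()
    if params.transform == "CCS":
        contrast, average = ccs_transform(a, b, params.ccs_k)
    else:
        contrast, average = ma_transform(a, b)
    points = np.column_stack([contrast, average])

    fit = select_component_count(contrast, params)
    comp_labels = label_components(fit, params)
    comp_assign = initial_assignment(fit, params)
    if not (comp_assign != -1).any():
        # pathological posterior landscape: seed with hard labels
        comp_assign = fit.hard_labels()
    scales = params.distance_scaling
    comp_assign = friends_of_friends_assign(points, comp_assign, scales)
    labels = np.array([comp_labels[j] for j in comp_assign], dtype=object)

    # two rounds of group statistics: the first confidence pass flags
    # gross outliers as N; refitting the biweight stats without them
    # removes their residual leverage on the scatter (one-step biweight
    # only downweights points near the rejection boundary), and the
    # refined stats drive the final confidence and later VINO scoring
    stats = compute_group_stats(points, labels, params)
    calls1, _ = confidence_scores(points, labels, stats, params)
    refined = compute_group_stats(points, calls1, params)
    for lab, center in stats.centers.items():  # keep groups emptied by the N pass
        if lab not in refined.centers:
            refined.centers[lab] = center
            refined.scatters[lab] = stats.scatters[lab]
            refined.counts[lab] = stats.counts[lab]
    calls, conf = confidence_scores(points, labels, refined, params)
    return ProbeCallResult(calls, conf, points, fit, refined, labels)


def call_genotypes(intensity_table, params: CallingParams | None = None, retained_strands=None):
    """Call genotypes for every probe set of an intensity table.

    Returns ``(calls, confidence)`` DataFrames (probe sets x samples)
    plus a dict of per-probe :class:`ProbeCallResult` diagnostics.  A
    per-probe failure yields an all-N row, never an aborted run.
    """
    caller = GenotypeCaller(params=params, retained_strands=retained_strands)
    caller.fit(intensity_table)
    return caller.calls_, caller.confidence_, caller.results_


class GenotypeCaller:
    """Scikit-learn style estimator wrapping the per-probe pipeline.

    Parameters mirror :class:`CallingParams`; after :meth:`fit` the
    calls are in ``calls_`` (DataFrame of A/H/B/N), confidences in
    ``confidence_``, and per-probe diagnostics in ``results_``.
    """

    def __init__(self, params: CallingParams | None = None, retained_strands=None):
        self.params = params
        self.retained_strands = retained_strands

    def get_params(self, deep=True):
        return {"params": self.params, "retained_strands": self.retained_strands}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, intensity_table, y=None):
        params = self.params or CallingParams()
        samples = intensity_table.sample_ids
        probe_ids = intensity_table.probe_ids
        calls = {}
        confs = {}
        results = {}
        skipped = []
        for pid in probe_ids:
            a_by_strand, b_by_strand = intensity_table.probe_intensities(pid)
            retained = None if self.retained_strands is None else self.retained_strands.get(pid)
            try:
                a, b = summarize_probe_set(a_by_strand, b_by_strand, retained)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = call_probe(a, b, params)
                calls[pid] = res.calls
                confs[pid] = res.confidence
                results[pid] = res
            except Exception as exc:  # per-probe failure -> all N
                skipped.append((pid, repr(exc)))
                calls[pid] = np.full(len(samples), NO_CALL, dtype=object)
                confs[pid] = np.zeros(len(samples))
        self.calls_ = pd.DataFrame.from_dict(calls, orient="index", columns=samples).loc[probe_ids]
        self.confidence_ = pd.DataFrame.from_dict(confs, orient="index", columns=samples).loc[probe_ids]
        self.results_ = results
        self.failed_probes_ = skipped
        if skipped:
            warnings.warn(f"{len(skipped)} probe set(s) failed and were called N")
        return self

    def fit_predict(self, intensity_table, y=None):
        return self.fit(intensity_table).calls_
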