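"""VINO detection: variable-intensity (off-target-variant) calls.

A VINO is a probe set showing a reproducible low-average-intensity
sample cluster caused by unmodeled variation in the probe's genomic
target.  Per sample the VINO score combines two tail probabilities:

    score = (1 - confidence) * Phi(z),   z = (mu_avg - avg) / sigma_avg

i.e. how far the sample sits from its genotype group's robust 2D
center (one minus the chi-square confidence) times the one-sided
probability of its average-intensity deficit below the group mean.
Both must be extreme for a V call; the threshold is deliberately
stringent (0.9999) so genotype calls are rarely sacrificed.

When at least one sample at a probe exceeds the threshold, the V
cluster is expanded: every sample with average intensity below the
across-sample mean is unassigned and the friends-of-friends accretion
re-run with the V seeds as an assignable group.  Samples accreting to
the V cluster become V; the rest keep their original call and
confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .calling import (
    CallingParams,
    GenotypeCaller,
    GroupStats,
    ProbeCallResult,
    friends_of_friends_assign,
)

__all__ = ["VinoParams", "vino_scores", "call_vinos", "vinotype_probe", "VinotypeCaller", "call_vinotypes"]


@dataclass
class VinoParams:
    vino_threshold: float = 0.9999

    def __post_init__(self):
        if not (0 < self.vino_threshold < 1):
            raise ValueError("vino_threshold must be in (0, 1)")


def vino_scores(points, labels, group_stats: GroupStats) -> np.ndarray:
    """Per-sample VINO score in [0, 1].

    ``labels`` are the genotype-group labels *before* the confidence
    stage turned low-confidence samples into N, so every sample has a
    group to be measured against.  A zero group SD in the average
    dimension is floored.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.asarray(labels, dtype=object)
    scores = np.zeros(len(pts))
    for lab, center in group_stats.centers.items():
        idx = np.flatnonzero(labels == lab)
        if idx.size == 0:
            continue
        scatter = group_stats.scatters[lab]
        inv = np.linalg.inv(scatter)
        diff = pts[idx] - center
        d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        conf = np.exp(-d2 / 2.0)
        sigma_avg = max(np.sqrt(scatter[1, 1]), 1e-6)
        z = (center[1] - pts[idx, 1]) / sigma_avg
        scores[idx] = (1.0 - conf) * norm.cdf(z)
    return scores


def call_vinos(points, calls, pre_n_labels, scores, params: VinoParams | None = None, scales=None):
    """Substitute V calls into a probe's genotype calls.

    If no score exceeds the threshold the vinotypes equal the
    genotypes.  Otherwise the super-threshold samples seed a V group;
    all samples whose average intensity falls below the across-sample
    mean are unassigned and re-attached by friends-of-friends with V as
    an assignable group.  Samples accreting to V become V; every other
    sample keeps its original call (and confidence) — vinotypes differ
    from genotypes only by V substitutions.
    """
    params = params or VinoParams()
    calls = np.asarray(calls, dtype=object)
    scores = np.asarray(scores, dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    vinotypes = calls.copy()
    seeds = scores > params.vino_threshold
    if not seeds.any():
        return vinotypes

    overall_mean = pts[:, 1].mean()
    stripped = (pts[:, 1] < overall_mean) & ~seeds
    pre_n = np.asarray(pre_n_labels, dtype=object)

    # groups for the second accretion pass: V plus the genotype groups of
    # the anchored (non-stripped, non-seed) samples
    group_names = ["V"] + sorted({str(g) for g in pre_n[~stripped & ~seeds]})
    group_index = {g: i for i, g in enumerate(group_names)}
    labels = np.full(len(calls), -1, dtype=int)
    labels[seeds] = group_index["V"]
    anchored = ~stripped & ~seeds
    for i in np.flatnonzero(anchored):
        labels[i] = group_index[str(pre_n[i])]
    labels = friends_of_friends_assign(pts, labels, scales)
    accreted_v = (labels == group_index["V"]) & ~seeds & stripped

    vinotypes[seeds | accreted_v] = "V"
    return vinotypes


def vinotype_probe(result: ProbeCallResult, params: VinoParams | None = None, scales=None):
    """VINO stage for one probe's calling result: (vinotypes, scores)."""
    scores = vino_scores(result.points, result.pre_n_labels, result.group_stats)
    vinotypes = call_vinos(result.points, result.calls, result.pre_n_labels, scores, params, scales)
    return vinotypes, scores


class VinotypeCaller:
    """Estimator producing both genotype and vinotype matrices.

    After :meth:`fit`: ``genotypes_``, ``vinotypes_`` (probe x sample
    call DataFrames), ``confidence_`` and ``vino_scores_``.
    """

    def __init__(self, params: CallingParams | None = None, vino_params: VinoParams | None = None, retained_strands=None):
        self.params = params
        self.vino_params = vino_params
        self.retained_strands = retained_strands

    def get_params(self, deep=True):
        return {
            "params": self.params,
            "vino_params": self.vino_params,
            "retained_strands": self.retained_strands,
        }

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, intensity_table, y=None):
        base = GenotypeCaller(params=self.params, retained_strands=self.retained_strands)
        base.fit(intensity_table)
        vparams = self.vino_params or VinoParams()
        scales = (self.params or CallingParams()).distance_scaling
        vinos = {}
        scores = {}
        for pid in base.calls_.index:
            res = base.results_.get(pid)
            if res is None:  # probe failed in the genotype stage
                vinos[pid] = base.calls_.loc[pid].to_numpy()
                scores[pid] = np.zeros(base.calls_.shape[1])
                continue
            v, s = vinotype_probe(res, vparams, scales)
            vinos[pid] = v
            scores[pid] = s
        cols = base.calls_.columns
        self.genotypes_ = base.calls_
        self.confidence_ = base.confidence_
        self.results_ = base.results_
        self.vinotypes_ = pd.DataFrame.from_dict(vinos, orient="index", columns=cols).loc[base.calls_.index]
        self.vino_scores_ = pd.DataFrame.from_dict(scores, orient="index", columns=cols).loc[base.calls_.index]
        return self

    def fit_predict(self, intensity_table, y=None):
        return self.fit(intensity_table).vinotypes_


def call_vinotypes(intensity_table, params: CallingParams | None = None, vino_params: VinoParams | None = None, retained_strands=None):
    """Functional wrapper: returns (genotypes, vinotypes, confidence, scores)."""
    caller = VinotypeCaller(params, vino_params, retained_strands).fit(intensity_table)
    return caller.genotypes_, caller.vinotypes_, caller.confidence_, caller.vino_scores_
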