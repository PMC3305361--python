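"""Probe and strand quality control.

Two filters, both computed from calls on a reference panel expected to
be homozygous (inbred strains):

* probe filter — flag probe sets where more than half of the non-N
  calls are heterozygous, or where only one genotype class appears
  (nothing to cluster); flagged probes are kept but marked so callers
  can drop them.
* strand filter — when a probe set's two strands disagree in cluster
  quality, drop the strand whose silhouette is below 0.7 when the
  other strand's silhouette exceeds it by more than 0.2.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calling import CallingParams, select_component_count, silhouette_score
from .transforms import ccs_transform, ma_transform

__all__ = ["flag_bad_probes", "strand_performance_filter", "strand_filter_table"]

SILHOUETTE_MIN = 0.7
SILHOUETTE_GAP = 0.2


def flag_bad_probes(calls: pd.DataFrame, het_fraction_threshold: float = 0.5) -> pd.DataFrame:
    """Per-probe flag + reason from a call matrix of an inbred panel.

    N calls are excluded from both the heterozygous fraction and the
    class count; an all-N probe is flagged with reason "no calls".
    The heterozygous rule is a strict > comparison.
    """
    flags = []
    for pid, row in calls.iterrows():
        vals = row.to_numpy(dtype=object)
        called = vals[vals != "N"]
        if called.size == 0:
            flags.append((pid, True, "no calls"))
            continue
        het_frac = float((called == "H").sum()) / called.size
        classes = set(called)
        if het_frac > het_fraction_threshold:
            flags.append((pid, True, f"heterozygous fraction {het_frac:.3f} > {het_fraction_threshold}"))
        elif len(classes) == 1:
            flags.append((pid, True, f"single genotype class {called[0]}"))
        else:
            flags.append((pid, False, ""))
    return pd.DataFrame(flags, columns=["probe_set_id", "flag", "reason"]).set_index("probe_set_id")


def strand_performance_filter(strand_silhouettes: dict) -> dict:
    """Keep/drop decision per strand from per-strand silhouette scores.

    A strand is dropped iff its silhouette is below 0.7 and the other
    strand's silhouette exceeds it by more than 0.2; with those
    thresholds at most one strand can be dropped.  Single-strand probes
    are kept unconditionally.  Missing silhouettes (no second cluster
    on that strand) count as 0.
    """
    strands = list(strand_silhouettes)
    if len(strands) == 1:
        return {strands[0]: True}
    sil = {s: (v if v is not None and np.isfinite(v) else 0.0) for s, v in strand_silhouettes.items()}
    keep = {}
    for s in strands:
        others = [sil[o] for o in strands if o != s]
        keep[s] = not (sil[s] < SILHOUETTE_MIN and max(others) - sil[s] > SILHOUETTE_GAP)
    if not any(keep.values()):  # cannot happen with gap > 0, but stay safe
        keep = {s: True for s in strands}
    return keep


def _contrast(a, b, params: CallingParams):
    if params.transform == "CCS":
        return ccs_transform(a, b, params.ccs_k)[0]
    return ma_transform(a, b)[0]


def strand_filter_table(intensity_table, params: CallingParams | None = None) -> pd.DataFrame:
    """Per-(probe, strand) report: silhouette and keep/drop decision.

    Genotype labels come from a preliminary mixture fit on the
    strand-averaged contrasts; each strand's own contrast values are
    then silhouette-scored against those shared labels, so a strand
    whose intensities do not separate the genotype groups scores near
    zero.  The keep/drop rule is :func:`strand_performance_filter`.
    """
    params = params or CallingParams()
    rows = []
    for pid in intensity_table.probe_ids:
        a_by_strand, b_by_strand = intensity_table.probe_intensities(pid)
        strands = list(a_by_strand)
        contrasts = {s: _contrast(a_by_strand[s], b_by_strand[s], params) for s in strands}
        self_sil = {}
        self_labels = {}
        for s in strands:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = select_component_count(contrasts[s], params)
            labels = fit.hard_labels()
            if fit.k < 2 or len(np.unique(labels)) < 2:
                self_sil[s], self_labels[s] = None, None
            else:
                self_sil[s] = silhouette_score(contrasts[s], labels)
                self_labels[s] = labels
        # reference strand = best self-clustering; the other strand is
        # scored against the reference labels ('forward' wins ties)
        ref = max(strands, key=lambda s: (-np.inf if self_sil[s] is None else self_sil[s], s == "forward"))
        sils = {}
        for s in strands:
            if s == ref or self_labels[ref] is None:
                sils[s] = self_sil[s]
            else:
                sils[s] = silhouette_score(contrasts[s], self_labels[ref])
        keep = strand_performance_filter(sils) if len(strands) > 1 else {strands[0]: True}
        for s in strands:
            rows.append((pid, s, np.nan if sils[s] is None else sils[s], keep[s]))
    return pd.DataFrame(rows, columns=["probe_set_id", "strand", "silhouette", "keep"]).set_index(
        ["probe_set_id", "strand"]
    )


def retained_strands_from_table(report: pd.DataFrame) -> dict:
    """Convert a strand report into the {probe_id: [strands]} mapping the caller takes."""
    out = {}
    for (pid, strand), row in report.iterrows():
        if row["keep"]:
            out.setdefault(pid, []).append(strand)
    return out
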