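"""Classification of hybridization-disrupting events.

Arrays that reduce genomic complexity by restriction-fragment
amplification hybridize poorly when the probe's target carries an
off-target variant (OTV) or when a restriction-site variant (RFLP)
pushes the fragment outside the optimal 50 bp - 1 kb window.  This
module classifies such events per probe set from variant and fragment
tables, and summarizes intensity and call rates by event class.

Event classes: ``central_otv`` (variant in the probe's central
region), ``edge_otv`` (within 3 bp of either probe end, minor effect),
``rflp_1_1.5k`` / ``rflp_gt1.5k`` (minimum fragment pushed above 1 kb /
1.5 kb), ``cut_in_probe`` (a new restriction site inside the probe),
plus the coverage sentinels ``inaccessible`` and ``low_coverage``, the
combination class ``multiple`` and ``none``.  Coordinates are 0-based,
half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "classify_variant_position",
    "classify_fragment",
    "detect_cut_in_probe",
    "classify_probe_set_event",
    "intensity_by_event_summary",
]

EDGE_BP = 3
OPTIMAL_MAX_BP = 1000
RFLP_SPLIT_BP = 1500


def classify_variant_position(probe_length: int, variant_offset: int) -> str:
    """Edge vs central OTV: edge iff within the outer 3 bp of either probe end."""
    if not 0 <= variant_offset < probe_length:
        raise ValueError(f"offset {variant_offset} out of range for probe length {probe_length}")
    if variant_offset < EDGE_BP or variant_offset >= probe_length - EDGE_BP:
        return "edge_otv"
    return "central_otv"


def classify_fragment(nsp_fragment_bp=None, sty_fragment_bp=None) -> str:
    """RFLP bin of the smallest available restriction fragment.

    <= 1 kb is within the optimal amplification range ('none');
    (1 kb, 1.5 kb] and > 1.5 kb form the two RFLP classes (the upper
    boundary of the first bin is closed at 1500 bp).  Both fragments
    absent means the locus is not amplifiable at all -> 'inaccessible'.
    """
    frags = [f for f in (nsp_fragment_bp, sty_fragment_bp) if f is not None and np.isfinite(f)]
    if not frags:
        return "inaccessible"
    m = min(frags)
    if m <= OPTIMAL_MAX_BP:
        return "none"
    if m <= RFLP_SPLIT_BP:
        return "rflp_1_1.5k"
    return "rflp_gt1.5k"


def detect_cut_in_probe(probe_interval, recognition_site_intervals) -> bool:
    """True iff any recognition-site interval overlaps the probe (half-open)."""
    ps, pe = probe_interval
    if pe < ps:
        raise ValueError(f"malformed probe interval {probe_interval}")
    for s, e in recognition_site_intervals:
        if e < s:
            raise ValueError(f"malformed site interval {(s, e)}")
        if s < pe and ps < e:
            return True
    return False


def classify_probe_set_event(per_strand_events: dict, coverage_flags=()) -> tuple[str, bool]:
    """Combine per-strand event lists into one (class, both_strands) pair.

    ``per_strand_events`` maps each retained strand to a list of base
    event classes observed on it.  Coverage flags ('inaccessible',
    'low_coverage') count as events.  Two or more distinct base classes
    -> 'multiple'; ``both_strands`` is true when every retained strand
    shows at least one event.
    """
    all_events = set(coverage_flags)
    strands_with_event = 0
    for strand, events in per_strand_events.items():
        events = [e for e in events if e and e != "none"]
        if events or coverage_flags:
            strands_with_event += 1
        all_events.update(events)
    if not all_events:
        return "none", False
    cls = all_events.pop() if len(all_events) == 1 else "multiple"
    both = strands_with_event == len(per_strand_events) and len(per_strand_events) > 0
    return cls, both


def _best_allele_mean_intensity(intensity_table, probe_id) -> float:
    """Mean intensity of the better-hybridizing allele across samples/strands."""
    a_by_strand, b_by_strand = intensity_table.probe_intensities(probe_id)
    a = float(np.mean([v for v in a_by_strand.values()]))
    b = float(np.mean([v for v in b_by_strand.values()]))
    return max(a, b)


def intensity_by_event_summary(intensity_table, probe_table, classifications: pd.Series, vinotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean best-allele intensity and V/N rate by OTV offset and fragment bin.

    Mirrors the three-panel structure: probes with an OTV are binned by
    the variant's distance to the nearest probe edge (0-12); probes
    without one are binned by minimum restriction fragment length in
    250-bp bins.  Empty bins are reported with count 0 and no mean.
    """
    rows = []
    bins: dict[tuple, list] = {}
    for pid in probe_table.index:
        cls = classifications.loc[pid]
        if cls in ("central_otv", "edge_otv"):
            L = int(probe_table.loc[pid, "probe_length"])
            off = int(probe_table.loc[pid, "target_offset"])
            dist = min(off, L - 1 - off)
            bins.setdefault(("otv_offset", str(dist)), []).append(pid)
        else:
            # the OTV panel carries a "none" bin; no-OTV probes are also
            # binned by their minimum fragment length
            bins.setdefault(("otv_offset", "none"), []).append(pid)
            frag = probe_table.loc[pid, ["nsp_fragment", "sty_fragment"]].min()
            bins.setdefault(("min_fragment", str(int(frag // 250) * 250)), []).append(pid)

    for (kind, bin_id), pids in sorted(bins.items()):
        means = [_best_allele_mean_intensity(intensity_table, pid) for pid in pids]
        calls = vinotypes.loc[pids].to_numpy(dtype=object)
        n_calls = calls.size
        vn = float(((calls == "V") | (calls == "N")).sum()) / n_calls if n_calls else np.nan
        rows.append((kind, bin_id, len(pids), float(np.mean(means)), vn))
    out = pd.DataFrame(rows, columns=["bin_type", "bin", "n_probes", "mean_best_allele_intensity", "vn_rate"])
    return out.set_index(["bin_type", "bin"])
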