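"""Synthetic intensity simulator.

Generates probe metadata, genotype/off-target-variant (OTV) truth and
per-strand A/B allele intensities with the statistical structure the
caller assumes, so every downstream stage is testable without real
array data.

The generative model works in the caller's own coordinates: each
genotype cluster has a configured (MA contrast, log2 average-intensity)
center and within-cluster SDs; a sampled (c, m) point is inverted
analytically to linear allele intensities a = (1 + c)·2^m,
b = (1 - c)·2^m.  On top of that:

* hom OTV carriers have both allele intensities multiplied by
  2^(-e·sigma_m), so their average-intensity deficit is exactly ``e``
  within-cluster SDs (e depends on the event class: central OTVs well
  above one SD, edge OTVs below one);
* het OTV carriers with an AB genotype have only the B-allele
  intensity knocked down (by 2^(-het_knockdown·e·sigma_m)), which
  flips the contrast toward the unaffected allele — the "cryptic
  VINO" geometry;
* restriction-fragment events (RFLP bins, cut-in-probe) act on both
  alleles regardless of the target genotype;
* smooth C+G and fragment-length biases and a per-array scale factor
  are applied multiplicatively.

Event-class effect sizes and noise magnitudes are implementer-chosen
defaults (documented in docs/methods.md); the cluster geometry and all
rates are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import IntensityTable

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_probe_metadata",
    "simulate_truth",
    "simulate_intensities",
    "simulate_dataset",
]

EVENT_CLASSES = ("central_otv", "edge_otv", "rflp_1_1.5k", "rflp_gt1.5k", "cut_in_probe")


def _default_event_mix():
    return {
        "central_otv": 0.40,
        "edge_otv": 0.20,
        "rflp_1_1.5k": 0.15,
        "rflp_gt1.5k": 0.15,
        "cut_in_probe": 0.10,
    }


def _default_effects():
    # average-intensity deficit of hom carriers, in within-cluster SDs;
    # a central mismatch knocks hybridization down severalfold (here
    # 5 * 0.25 = 1.25 log2 units, i.e. ~2.4x), edge mismatches barely
    return {
        "central_otv": 5.0,
        "edge_otv": 0.5,
        "rflp_1_1.5k": 1.2,
        "rflp_gt1.5k": 3.0,
        "cut_in_probe": 5.0,
    }


def _default_geometry():
    # genotype -> (MA contrast, log2 average intensity)
    return {"A": (0.65, 11.0), "H": (0.0, 11.2), "B": (-0.65, 11.0)}


@dataclass
class SimulationConfig:
    """All knobs of the generative model; defaults are the study conditions."""

    n_probes: int = 200
    n_samples: int = 96
    seed: int = 0
    allele_freq_range: tuple[float, float] = (0.2, 0.8)
    het_sample_fraction: float = 0.25
    otv_probe_rate: float = 0.1
    otv_carrier_freq: float = 0.2
    event_class_mix: dict = field(default_factory=_default_event_mix)
    cluster_geometry: dict = field(default_factory=_default_geometry)
    cluster_sd: tuple[float, float] = (0.05, 0.25)
    otv_effect_sd: dict = field(default_factory=_default_effects)
    het_knockdown: float = 4.0
    cg_bias_coeffs: tuple = (0.3, -0.2)
    fraglen_bias_coeffs: tuple = (-0.25,)
    array_scale_sd: float = 0.1
    background_fraction: float = 0.2
    optimal_fragment_fraction: float = 0.9
    strand_noise_multiplier: dict = field(default_factory=lambda: {"forward": 1.0, "reverse": 1.0})

    def __post_init__(self):
        for name in ("het_sample_fraction", "otv_probe_rate", "otv_carrier_freq", "optimal_fragment_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")
        lo, hi = self.allele_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"allele_freq_range must be an ordered pair in [0, 1], got {self.allele_freq_range}")
        if abs(sum(self.event_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("event_class_mix must sum to 1")
        if set(self.event_class_mix) - set(EVENT_CLASSES):
            raise ValueError(f"event_class_mix keys must be among {EVENT_CLASSES}")
        if any(sd < 0 for sd in self.cluster_sd):
            raise ValueError("cluster_sd entries must be >= 0")
        if self.n_probes < 0 or self.n_samples < 0:
            raise ValueError("n_probes and n_samples must be non-negative")


@dataclass
class TruthSet:
    """Ground truth backing a simulated intensity table."""

    genotypes: pd.DataFrame  # probe x sample, chars A/H/B
    otv_state: pd.DataFrame  # probe x sample, none/het/hom
    event_class: pd.Series  # per probe, event class or 'none'
    probe_table: pd.DataFrame
    het_samples: np.ndarray  # boolean per sample

    def __post_init__(self):
        if self.genotypes.shape != self.otv_state.shape:
            raise ValueError("genotypes and otv_state dimensions disagree")
        if len(self.event_class) != len(self.genotypes):
            raise ValueError("event_class length disagrees with genotypes")
        inbred = ~self.het_samples
        if (self.genotypes.loc[:, inbred] == "H").any().any():
            raise ValueError("inbred samples may not carry AB genotypes")
        het_state = self.otv_state.to_numpy() == "het"
        if het_state[:, inbred].any():
            raise ValueError("otv_state het is only allowed for heterozygous-capable samples")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_probe_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Draw the probe annotation table.

    Probe lengths are uniform on 21-25 nt; a configurable majority of
    probe sets have their smallest NspI/StyI fragment inside the
    optimal 50 bp - 1 kb amplification window, the rest above it; C+G
    fractions are beta-distributed in (0, 1).  ``target_offset`` is the
    0-based offset of the probe's OTV site (meaningful only for probes
    the truth set marks as OTV-carrying).
    """
    rng = _rng(config, 1)
    n = config.n_probes
    probe_ids = [f"PS{i:06d}" for i in range(n)]
    length = rng.integers(21, 26, size=n)
    cg = np.clip(rng.beta(10, 10, size=n), 1e-3, 1 - 1e-3)
    optimal = rng.random(n) < config.optimal_fragment_fraction
    nsp = np.where(optimal, rng.integers(100, 1001, size=n), rng.integers(1001, 2501, size=n))
    sty = np.where(optimal, rng.integers(100, 1001, size=n), nsp + rng.integers(0, 1000, size=n))
    offset = np.array([rng.integers(0, L) for L in length], dtype=int)
    return pd.DataFrame(
        {
            "probe_length": length,
            "cg_content": cg,
            "nsp_fragment": nsp,
            "sty_fragment": sty,
            "target_offset": offset,
        },
        index=pd.Index(probe_ids, name="probe_set_id"),
    )


def simulate_truth(config: SimulationConfig, probe_table: pd.DataFrame | None = None) -> TruthSet:
    """Draw genotype and OTV truth.

    Per-probe B-allele frequencies are uniform on ``allele_freq_range``.
    Inbred samples are AA/BB; heterozygous-capable samples follow
    Hardy-Weinberg.  OTV probes are Bernoulli(``otv_probe_rate``) with
    an event class drawn from ``event_class_mix``; carriers are
    Bernoulli(``otv_carrier_freq``) per sample, 'hom' for inbred and
    'het' for heterozygous-capable carriers.
    """
    if probe_table is None:
        probe_table = simulate_probe_metadata(config)
    rng = _rng(config, 2)
    n_p, n_s = config.n_probes, config.n_samples
    sample_ids = [f"S{j:03d}" for j in range(n_s)]
    het_samples = rng.random(n_s) < config.het_sample_fraction

    freqs = rng.uniform(*config.allele_freq_range, size=n_p)
    geno = np.empty((n_p, n_s), dtype=object)
    u = rng.random((n_p, n_s))
    f = freqs[:, None]
    # inbred: BB with prob f else AA; het-capable: Hardy-Weinberg
    inbred_calls = np.where(u < f, "B", "A")
    hw = np.select([u < (1 - f) ** 2, u < (1 - f) ** 2 + 2 * f * (1 - f)], ["A", "H"], default="B")
    geno[:, het_samples] = hw[:, het_samples]
    geno[:, ~het_samples] = inbred_calls[:, ~het_samples]

    otv_probe = rng.random(n_p) < config.otv_probe_rate
    classes = list(config.event_class_mix)
    probs = np.array([config.event_class_mix[c] for c in classes])
    event = np.where(otv_probe, rng.choice(classes, size=n_p, p=probs), "none")
    carrier = (rng.random((n_p, n_s)) < config.otv_carrier_freq) & otv_probe[:, None]
    state = np.full((n_p, n_s), "none", dtype=object)
    state[carrier & ~het_samples[None, :]] = "hom"
    state[carrier & het_samples[None, :]] = "het"

    idx = probe_table.index
    return TruthSet(
        genotypes=pd.DataFrame(geno, index=idx, columns=sample_ids),
        otv_state=pd.DataFrame(state, index=idx, columns=sample_ids),
        event_class=pd.Series(event, index=idx, name="event_class"),
        probe_table=probe_table,
        het_samples=het_samples,
    )


def _bias_log2(config: SimulationConfig, probe_table: pd.DataFrame) -> np.ndarray:
    """Smooth per-probe log2 bias from C+G content and fragment length."""
    cg = probe_table["cg_content"].to_numpy(dtype=float)
    z = cg - 0.5
    bias = np.zeros(len(probe_table))
    for p, coef in enumerate(config.cg_bias_coeffs, start=1):
        bias += coef * z**p
    min_frag = probe_table[["nsp_fragment", "sty_fragment"]].min(axis=1).to_numpy(dtype=float)
    zf = np.log2(min_frag / 500.0)
    for p, coef in enumerate(config.fraglen_bias_coeffs, start=1):
        bias += coef * zf**p
    return bias


def simulate_intensities(truth: TruthSet, config: SimulationConfig) -> IntensityTable:
    """Emit per-strand A/B linear intensities for a truth set."""
    n_p, n_s = truth.genotypes.shape
    if (n_p, n_s) != (config.n_probes, config.n_samples):
        raise ValueError("truth dimensions disagree with config")
    rng = _rng(config, 3)
    sd_c, sd_m = config.cluster_sd
    geno = truth.genotypes.to_numpy()
    state = truth.otv_state.to_numpy()
    event = truth.event_class.to_numpy()
    bias = _bias_log2(config, truth.probe_table)
    scale = rng.normal(0.0, config.array_scale_sd, size=n_s) if config.array_scale_sd > 0 else np.zeros(n_s)

    centers_c = np.vectorize(lambda g: config.cluster_geometry[g][0], otypes=[float])(geno)
    centers_m = np.vectorize(lambda g: config.cluster_geometry[g][1], otypes=[float])(geno)

    effect = np.vectorize(lambda e: config.otv_effect_sd.get(e, 0.0), otypes=[float])(event)
    is_rflp = np.isin(event, ["rflp_1_1.5k", "rflp_gt1.5k", "cut_in_probe"])

    rows = {}
    strands = ("forward", "reverse")
    for strand in strands:
        mult = config.strand_noise_multiplier.get(strand, 1.0)
        c = centers_c + rng.normal(0.0, sd_c * mult, size=(n_p, n_s)) if sd_c > 0 else centers_c.copy()
        m = centers_m + rng.normal(0.0, sd_m * mult, size=(n_p, n_s)) if sd_m > 0 else centers_m.copy()
        c = np.clip(c, -0.999, 0.999)
        a0 = (1.0 + c) * 2.0**m
        b0 = (1.0 - c) * 2.0**m

        # split each allele signal into specific hybridization plus a
        # non-specific background floor; events knock down the specific
        # part only, so strong OTVs also compress the contrast toward 0
        # ("eliminate the contrast") as the background takes over
        bgf = config.background_fraction
        bg = bgf * 2.0**m
        s_a = np.maximum(a0 - bg, 0.0)
        s_b = np.maximum(b0 - bg, 0.0)

        e = effect[:, None]
        hom = state == "hom"
        het = state == "het"

        def total_factor(eff_sd):
            # specific-signal factor giving a total-intensity deficit of
            # exactly eff_sd within-cluster SDs, saturating at the floor
            return np.maximum((2.0 ** (-eff_sd * sd_m) - bgf) / (1.0 - bgf), 0.0)

        # hom carriers (all classes) and het carriers of fragment-level
        # events (one of two fragments affected -> half strength): both
        # allele probes share the target fragment
        f_both = np.where(hom, total_factor(e), 1.0)
        f_both = np.where(het & is_rflp[:, None], total_factor(e / 2.0), f_both)
        # het OTV in a homozygous target genotype: one of two haplotypes
        # affected, both allele probes see half the knockdown
        het_probe_otv = het & ~is_rflp[:, None]
        f_both = np.where(het_probe_otv & (geno != "H"), total_factor(e / 2.0), f_both)
        # het carriers of within-probe OTVs with a heterozygous target:
        # the OTV rides the B haplotype, so the B allele probe loses its
        # only specific template -- the cryptic-VINO geometry
        f_b_only = np.where(
            het_probe_otv & (geno == "H"), 2.0 ** (-config.het_knockdown * e * sd_m), 1.0
        )

        a = s_a * f_both + bg
        b = s_b * f_both * f_b_only + bg

        gain = 2.0 ** (bias[:, None] + scale[None, :])
        rows[(strand, "A")] = a * gain
        rows[(strand, "B")] = b * gain

    tuples = [(pid, strand, allele) for pid in truth.genotypes.index for strand in strands for allele in ("A", "B")]
    names = ["probe_set_id", "strand", "allele"]
    if tuples:
        index = pd.MultiIndex.from_tuples(tuples, names=names)
    else:
        index = pd.MultiIndex.from_arrays([[], [], []], names=names)
    data = np.empty((len(index), n_s))
    for i, pid in enumerate(truth.genotypes.index):
        for s_i, strand in enumerate(strands):
            for a_i, allele in enumerate(("A", "B")):
                data[i * 4 + s_i * 2 + a_i] = rows[(strand, allele)][i]
    values = pd.DataFrame(data, index=index, columns=truth.genotypes.columns)
    return IntensityTable(values)


def simulate_dataset(config: SimulationConfig):
    """Convenience: probe table, truth and intensities in one call."""
    probe_table = simulate_probe_metadata(config)
    truth = simulate_truth(config, probe_table)
    intensities = simulate_intensities(truth, config)
    return probe_table, truth, intensities
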