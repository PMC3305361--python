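"""Readers and writers for the on-disk formats.

Everything tabular is tab-separated UTF-8 text.  Genotype calls are
stored as single characters (A = AA, H = AB, B = BB, N = no-call,
V = VINO); an explicit N marks missing data ('.' is not accepted).
Intensity tables have one row per (probe set, strand, allele) with one
column per sample; probe tables are indexed by probe set id.

VINO presence/absence can be exported as a NEXUS DATA block for tree
building: each marker becomes one synthetic binary character, C where
the call is V and G otherwise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTable",
    "read_intensity_table",
    "write_intensity_table",
    "read_call_matrix",
    "write_call_matrix",
    "read_probe_table",
    "write_probe_table",
    "encode_vinotype_characters",
    "write_nexus",
    "load_example_crosstab",
]

STRANDS = ("forward", "reverse")
ALLELES = ("A", "B")
CALL_SYMBOLS = ("A", "H", "B", "N", "V")


@dataclass
class IntensityTable:
    """Per (probe set, strand, allele) x sample linear intensities.

    ``values`` is a DataFrame whose row index is a MultiIndex
    (probe_set_id, strand, allele) and whose columns are sample ids.
    Each probe set carries one or two strands, each with both alleles;
    all intensities are strictly positive.
    """

    values: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self):
        df = self.values
        if df.index.nlevels != 3:
            raise ValueError("index must be (probe_set_id, strand, allele)")
        if df.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if len(df) and (df.to_numpy(dtype=float) <= 0).any():
            bad = np.argwhere(df.to_numpy(dtype=float) <= 0)[0]
            raise ValueError(f"non-positive intensity at row {df.index[bad[0]]}")
        strands = df.index.get_level_values(1)
        if len(df) and not set(strands) <= set(STRANDS):
            raise ValueError(f"strand must be one of {STRANDS}")
        # every present (probe, strand) must have both alleles
        pairs = df.groupby(level=[0, 1]).size()
        if len(df) and not (pairs == 2).all():
            missing = pairs[pairs != 2].index[0]
            raise ValueError(f"probe set {missing[0]} strand {missing[1]} is missing an allele row")

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> list:
        return list(pd.unique(self.values.index.get_level_values(0)))

    def probe_intensities(self, probe_id):
        """Return ({strand: A-intensities}, {strand: B-intensities}) for a probe set."""
        sub = self.values.loc[probe_id]
        a, b = {}, {}
        for strand in pd.unique(sub.index.get_level_values(0)):
            a[strand] = sub.loc[(strand, "A")].to_numpy(dtype=float)
            b[strand] = sub.loc[(strand, "B")].to_numpy(dtype=float)
        return a, b

    def strands_for(self, probe_id) -> list:
        return list(pd.unique(self.values.loc[probe_id].index.get_level_values(0)))


def write_intensity_table(table: IntensityTable, path):
    df = table.values.reset_index()
    df.columns = ["probe_set_id", "strand", "allele"] + list(table.values.columns)
    df.to_csv(path, sep="\t", index=False)


def read_intensity_table(path) -> IntensityTable:
    df = pd.read_csv(path, sep="\t", dtype={"probe_set_id": str})
    required = ["probe_set_id", "strand", "allele"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: first three columns must be {required}")
    for lineno, value in enumerate(df["allele"], start=2):
        if value not in ALLELES:
            raise ValueError(f"{path}: line {lineno}: allele must be A or B, got {value!r}")
    body = df.set_index(required)
    num = body.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        row = int(np.argwhere(num.isna().to_numpy())[0][0])
        raise ValueError(f"{path}: line {row + 2}: non-numeric intensity")
    if (num.to_numpy() <= 0).any():
        row = int(np.argwhere((num.to_numpy() <= 0))[0][0])
        raise ValueError(f"{path}: line {row + 2}: non-positive intensity")
    return IntensityTable(num)


_CALL_HEADER = "# genotype calls: A=AA, H=AB, B=BB, N=no-call, V=VINO\n"


def write_call_matrix(calls: pd.DataFrame, path):
    """Write a probe x sample call matrix with its encoding documented in the header."""
    bad = set(np.unique(calls.to_numpy(dtype=object))) - set(CALL_SYMBOLS)
    if bad:
        raise ValueError(f"invalid call symbols: {sorted(bad)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_CALL_HEADER)
        calls.rename_axis("probe_set_id").to_csv(fh, sep="\t")


def read_call_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    bad = set(np.unique(df.to_numpy(dtype=object))) - set(CALL_SYMBOLS)
    if bad:
        raise ValueError(f"{path}: invalid call symbols: {sorted(bad)}")
    return df


PROBE_COLUMNS = ["probe_length", "cg_content", "nsp_fragment", "sty_fragment", "target_offset"]


def write_probe_table(probe_table: pd.DataFrame, path):
    probe_table.rename_axis("probe_set_id").to_csv(path, sep="\t")


def read_probe_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_set_id")


# ---------------------------------------------------------------------------
# NEXUS export of VINO presence/absence characters


def encode_vinotype_characters(vinotypes: pd.DataFrame) -> pd.DataFrame:
    """Binary-encode vinotypes for tree building: C where V, G otherwise."""
    return vinotypes.where(vinotypes == "V", "G").where(vinotypes != "V", "C")


def write_nexus(characters: pd.DataFrame, path, combine_with: pd.DataFrame | None = None, missing: str = "N"):
    """Write a marker x taxon character matrix as a MRBAYES-style NEXUS DATA block.

    ``characters`` rows are markers, columns are taxa.  When
    ``combine_with`` (same shape/labels) is given, its characters are
    interleaved adjacent to their source markers so NCHAR doubles; the
    synthetic markers sit at a nominal 0.001 cM offset, recorded as a
    comment (NEXUS characters are unordered).
    """
    taxa = list(characters.columns)
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxa must be unique")
    mat = characters
    comment = ""
    if combine_with is not None:
        if combine_with.shape != characters.shape:
            raise ValueError("combine_with must match the character matrix shape")
        rows = []
        index = []
        for marker in characters.index:
            rows.append(characters.loc[marker])
            index.append(str(marker))
            rows.append(combine_with.loc[marker].rename(f"{marker}_vino"))
            index.append(f"{marker}_vino")
        mat = pd.DataFrame(rows, index=index)
        comment = "[synthetic *_vino characters placed 0.001 cM from their source markers]\n"
    arr = mat.to_numpy(dtype=object)
    lengths = {len(str(v)) for v in arr.ravel()}
    if lengths != {1}:
        raise ValueError("characters must be single symbols")
    ntax, nchar = len(taxa), len(mat)
    pad = max(len(str(t)) for t in taxa) + 2
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n")
        fh.write(comment)
        fh.write("BEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={ntax} NCHAR={nchar};\n")
        fh.write(f"  FORMAT DATATYPE=DNA MISSING={missing} GAP=-;\n")
        fh.write("  MATRIX\n")
        for taxon in taxa:
            seq = "".join(str(v) for v in mat[taxon])
            fh.write(f"    {str(taxon).ljust(pad)}{seq}\n")
        fh.write("  ;\nEND;\n")


# ---------------------------------------------------------------------------
# Bundled worked-example cross-tabulations


def load_example_crosstab(name: str) -> pd.DataFrame:
    """Load one of the bundled call cross-tabulations (counts DataFrame).

    Available names: ``pairwise_mdg_alchemy``, ``pairwise_mdg_brlmm``,
    ``pairwise_alchemy_brlmm`` (method-vs-method genotype calls from a
    351-sample mouse diversity panel), ``sequence_truth_mdg``,
    ``sequence_truth_alchemy``, ``sequence_truth_brlmm`` (array calls
    vs whole-genome-sequence genotype classes for 14 inbred strains)
    and ``f1_parental`` (parental call pairs vs observed F1 calls).
    """
    ref = importlib.resources.files("vinotyper.data") / f"{name}.tsv"
    if not ref.is_file():
        raise FileNotFoundError(f"no bundled cross-tab named {name!r}")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    return df.astype(np.int64)
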