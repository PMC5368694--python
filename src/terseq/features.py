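"""Per-operon sequence covariates: CAI, ITE and GC content.

The codon adaptation index is the geometric mean, over the sense codons
of a coding sequence, of each codon's *relative adaptiveness* — its
usage frequency divided by the highest frequency in its synonymous
family.  The index of translation elongation (ITE) shares the same
geometric-mean form but runs over an externally supplied codon weight
set; this module treats both as table-driven scores.  RNA folding
energy is deliberately *not* computed here: :func:`load_folding_energies`
accepts precomputed per-sequence energies from a TSV instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.Data import CodonTable
from Bio.SeqUtils import gc_fraction

__all__ = [
    "CodonWeightTable",
    "load_codon_usage",
    "relative_adaptiveness",
    "cai",
    "ite",
    "gc_content",
    "load_folding_energies",
    "compute_feature_table",
    "SENSE_CODONS",
    "STOP_CODONS",
]

# Bacterial genetic code (NCBI translation table 11)
_TABLE = CodonTable.unambiguous_dna_by_id[11]
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class CodonWeightTable:
    """Relative-adaptiveness weights w in (0, 1] for the 61 sense codons."""

    weights: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.weights)
        if missing:
            raise ValueError(f"weights missing for codons: {sorted(missing)}")
        for fam in _FAMILIES.values():
            wmax = max(self.weights[c] for c in fam)
            if not math.isclose(wmax, 1.0, rel_tol=1e-9):
                raise ValueError(
                    f"synonymous family {fam} maximum weight is {wmax}, not 1")
        if any(not 0 < self.weights[c] <= 1 + 1e-12 for c in SENSE_CODONS):
            raise ValueError("weights must lie in (0, 1]")


def load_codon_usage(path=None) -> dict[str, float]:
    """Codon usage frequencies from a two-column TSV (codon, count).

    Defaults to the packaged E. coli K-12 usage table (Kazusa-style
    frequencies per thousand codons).
    """
    if path is None:
        path = resources.files("terseq.data") / "ecoli_codon_usage.tsv"
    df = pd.read_csv(path, sep="\t")
    codon_col, freq_col = df.columns[0], df.columns[1]
    return {str(c).upper().replace("U", "T"): float(f)
            for c, f in zip(df[codon_col], df[freq_col])}


def relative_adaptiveness(frequencies: dict[str, float],
                          source: str = "") -> CodonWeightTable:
    """w_c = f_c / max(f over the codon's synonymous family).

    Codons never observed (f = 0) get the smallest positive weight in
    their family divided by 2, a common pseudo-weight, so geometric
    means stay finite; a family with no observed codon at all is an
    error.
    """
    weights: dict[str, float] = {}
    for fam in _FAMILIES.values():
        f = {c: float(frequencies.get(c, 0.0)) for c in fam}
        if any(v < 0 for v in f.values()):
            raise ValueError("codon frequencies must be nonnegative")
        fmax = max(f.values())
        if fmax <= 0:
            raise ValueError(f"synonymous family {fam} has all-zero frequency")
        nonzero_min = min(v for v in f.values() if v > 0)
        for c in fam:
            weights[c] = f[c] / fmax if f[c] > 0 else 0.5 * nonzero_min / fmax
    return CodonWeightTable(weights=weights, source=source)


def _codons(sequence: str, label: str) -> list[str]:
    seq = sequence.upper().replace("U", "T")
    rem = len(seq) % 3
    if rem:
        warnings.warn(f"{label}: trimming {rem} trailing nt to a codon multiple",
                      stacklevel=3)
        seq = seq[:len(seq) - rem]
    out = []
    n_ambig = 0
    n_stop = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if any(b not in "ACGT" for b in codon):
            n_ambig += 1
            continue
        if codon in STOP_CODONS:
            n_stop += 1
            continue
        out.append(codon)
    if n_ambig:
        warnings.warn(f"{label}: skipped {n_ambig} codons with ambiguous bases",
                      stacklevel=3)
    if n_stop > 1 or (n_stop == 1 and not seq.endswith(tuple(STOP_CODONS))):
        warnings.warn(f"{label}: internal stop codons in frame", stacklevel=3)
    return out


def _geometric_mean_score(sequence: str, weights: dict[str, float],
                          label: str) -> float:
    codons = _codons(sequence, label)
    if not codons:
        raise ValueError(f"{label}: no scorable codons in sequence")
    log_sum = sum(math.log(weights[c]) for c in codons)
    return math.exp(log_sum / len(codons))


def cai(sequence: str, table: CodonWeightTable) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Stop codons and codons containing ambiguous bases are excluded;
    single-codon families (ATG, TGG) contribute weight 1.
    """
    return _geometric_mean_score(sequence, table.weights, "CAI")


def ite(sequence: str, table: CodonWeightTable) -> float:
    """Index of translation elongation over a supplied codon weight set."""
    return _geometric_mean_score(sequence, table.weights, "ITE")


def gc_content(sequence: str) -> float:
    """Fraction of G and C bases (ambiguous S counts as GC)."""
    return float(gc_fraction(sequence))


def load_folding_energies(path) -> dict[str, float]:
    """Precomputed RNA folding energies (kcal/mol) from a TSV.

    Column 1 is the operon identifier, column 2 the energy.  Folding
    energies come from an external thermodynamic tool; this package only
    joins them into the feature table.
    """
    df = pd.read_csv(path, sep="\t")
    return {str(k): float(v) for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])}


def compute_feature_table(sequences: dict[str, str],
                          cai_table: CodonWeightTable,
                          ite_table: CodonWeightTable | None = None,
                          folding_energies: dict[str, float] | None = None,
                          extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per operon: cai, ite, gc_fraction and optional covariates.

    ``extra`` (indexed by operon or with an ``operon`` column) can carry
    regulator/sigma-factor flags, upregulation, max fold change, etc.
    """
    rows = []
    for name, seq in sequences.items():
        row = {"operon": name,
               "cai": cai(seq, cai_table),
               "gc_fraction": gc_content(seq)}
        if ite_table is not None:
            row["ite"] = ite(seq, ite_table)
        if folding_energies is not None:
            row["folding_energy"] = folding_energies.get(name)
        rows.append(row)
    df = pd.DataFrame(rows)
    if extra is not None:
        extra = extra.reset_index() if extra.index.name == "operon" else extra
        df = df.merge(extra, on="operon", how="left")
    return df
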