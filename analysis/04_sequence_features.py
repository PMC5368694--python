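"""Sequence covariates for the synthetic cohort: CAI, ITE, GC.

The cohort has no real genomic sequences, so this script generates a
random coding sequence per operon (GC content varying across operons,
independent of the operon's kinetics by construction — which is what
the null-association checks downstream rely on).  CAI uses the packaged
E. coli K-12 codon usage table; ITE uses a synthetic stand-in weight
set derived by jittering those frequencies, since the published ITE
weight data set is an external input.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from terseq.features import (SENSE_CODONS, compute_feature_table,
                             load_codon_usage, relative_adaptiveness)

ROOT = Path(__file__).resolve().parents[1]


def random_coding_sequence(rng: np.random.Generator, n_codons: int,
                           gc_bias: float) -> str:
    """Codon sequence with composition tilted toward/away from GC."""
    codons = list(SENSE_CODONS)
    gc = np.array([sum(b in "GC" for b in c) / 3 for c in codons])
    w = np.exp(gc_bias * gc)
    return "".join(rng.choice(codons, size=n_codons, p=w / w.sum()))


def synthetic_ite_weights(rng: np.random.Generator):
    """Stand-in ITE weight table: jittered copy of the usage table."""
    freqs = load_codon_usage()
    jittered = {c: f * rng.lognormal(0.0, 0.35) for c, f in freqs.items()}
    return relative_adaptiveness(jittered, source="synthetic-ite")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    truth = pd.read_csv(args.results / "truth.tsv", sep="\t")
    rng = np.random.default_rng(args.seed)
    seqs = {r.operon: random_coding_sequence(rng, max(int(r.length) // 3, 50),
                                             gc_bias=rng.uniform(-1.5, 1.5))
            for r in truth.itertuples()}

    cai_table = relative_adaptiveness(load_codon_usage(), source="ecoli-k12")
    ite_table = synthetic_ite_weights(rng)

    extra = pd.DataFrame({
        "operon": truth.operon,
        "upregulated": truth.direction == "increase",
        # steady-state fold change and peak expression from the truth table
        "max_fc": (truth.s_b + truth.s_a) / truth.s_b,
        "max_rpkm": (truth.s_b + truth.s_a) / (truth.mu + truth.gamma),
    })
    df = compute_feature_table(seqs, cai_table, ite_table=ite_table,
                               extra=extra)
    df.to_csv(args.results / "features.tsv", sep="\t", index=False)
    print(f"computed CAI/ITE/GC for {len(df)} operons "
          f"(CAI {df.cai.min():.3f}-{df.cai.max():.3f}, "
          f"GC {df.gc_fraction.min():.2f}-{df.gc_fraction.max():.2f})")
    print(f"wrote features.tsv to {args.results}")


if __name__ == "__main__":
    main()
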