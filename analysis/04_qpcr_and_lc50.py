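"""ddCt fold changes of the assayed miRNAs/genes and the LC50 of the dose curve.

miRNAs (miR-124, miR-155) are normalized to RNU48; osteogenic genes (RUNX2,
RANKL, BGLAP, OPG) to RPII + HPRT. Fold changes are signed (down-regulation
negative, |fc| >= 1).

Reads results/synthetic/, writes results/fold_changes.tsv.
"""

from pathlib import Path

import pandas as pd

from fluoro_sncrna import qpcr
from fluoro_sncrna.pipeline import GENE_REFS, MIRNA_REFS, TRUE_FC_GENES, TRUE_FC_MIRNA

ROOT = Path(__file__).resolve().parent.parent / "results"
IN = ROOT / "synthetic"

frames = []
for dose in ("8mg", "20mg"):
    table = qpcr.read_ct_tsv(IN / f"ct_{dose}.tsv")
    true_fc = {**TRUE_FC_MIRNA[dose], **TRUE_FC_GENES[dose]}
    fc = qpcr.fold_change_table(table, sorted(true_fc), MIRNA_REFS + GENE_REFS, dose=dose)
    fc["true_fc"] = fc["gene"].map(true_fc)
    frames.append(fc)
    for _, row in fc.iterrows():
        print(f"{dose:>5} {row['gene']:>8}: fc = {row['fc_signed']:+.2f} "
              f"(±{row['dispersion']:.2f}), generating truth {row['true_fc']:+.2f}")

pd.concat(frames, ignore_index=True).to_csv(ROOT / "fold_changes.tsv", sep="\t", index=False)

via = pd.read_csv(IN / "viability.tsv", sep="\t")
lc50 = qpcr.lc50_interpolate(via["dose_mg_per_l"].tolist(), via["viability"].tolist())
print(f"LC50 (log-linear interpolation): {lc50:.1f} mg/L")
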