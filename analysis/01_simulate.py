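"""Generate all synthetic study inputs with planted ground truth.

Emulated conditions: a 5639-probe-style 3-group array experiment at desk
scale (500 probes, 3 samples per group, 10% planted differential probes at
|log2 FC| = 2), 347 C/D-box snoRNA probe sequences with 15 planted long
outliers and UG enrichment, Ct tables for two NaF doses whose true signed
fold changes are known, and an MTT dose-viability curve with LC50 40 mg/L.

Writes results/synthetic/: matrix.tsv, samples.tsv, truth_de.tsv,
snorna_cd.fasta, regulation.tsv, ct_8mg.tsv, ct_20mg.tsv, viability.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from fluoro_sncrna import pipeline, synthio

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 17
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

cfg = pipeline.PipelineConfig(seed=SEED)

matrix, truth = synthio.gen_probe_matrix(
    synthio.MatrixGenSpec(
        n_probes=cfg.n_probes, group_sizes=cfg.group_sizes, de_fraction=cfg.de_fraction,
        effect_log2=cfg.effect_log2, noise_sd=cfg.noise_sd, seed=SEED,
    )
)
synthio.write_matrix_tsv(matrix, OUT / "matrix.tsv", OUT / "samples.tsv")
truth.to_csv(OUT / "truth_de.tsv", sep="\t", index=False)
print(f"probe matrix: {matrix.values.shape[0]} probes x {matrix.values.shape[1]} samples, "
      f"{len(truth)} planted DE probes")

rng = np.random.default_rng(SEED + 1)
n_total = cfg.n_core_snorna + cfg.n_outlier_snorna
seqs = synthio.gen_snorna_set(
    synthio.SnoRNAGenSpec(
        n_core=cfg.n_core_snorna, n_outliers=cfg.n_outlier_snorna,
        c_box_count_per_seq=1, d_box_counts=rng.integers(0, 6, size=n_total).tolist(),
        ug_enrichment=cfg.ug_enrichment, seed=SEED + 1,
    )
)
synthio.write_fasta(seqs, OUT / "snorna_cd.fasta")
pd.DataFrame(
    [(s.id, dose, d) for s in seqs for dose, d in (s.regulation or {}).items()],
    columns=["probe_id", "dose", "direction"],
).to_csv(OUT / "regulation.tsv", sep="\t", index=False)
print(f"snoRNA set: {len(seqs)} sequences ({cfg.n_outlier_snorna} planted long outliers)")

for i, dose in enumerate(("8mg", "20mg")):
    true_fc = {**pipeline.TRUE_FC_MIRNA[dose], **pipeline.TRUE_FC_GENES[dose]}
    table = synthio.gen_ct_table(
        synthio.CtGenSpec(
            genes=sorted(true_fc), reference_genes=pipeline.MIRNA_REFS + pipeline.GENE_REFS,
            true_fc_signed=true_fc, replicates=cfg.qpcr_replicates,
            noise_sd=cfg.qpcr_noise_sd, seed=SEED + 3 + i,
        )
    )
    table.to_csv(OUT / f"ct_{dose}.tsv", sep="\t", index=False)
    print(f"Ct table {dose}: {len(table)} rows, true fold changes {true_fc}")

synthio.gen_viability_table().to_csv(OUT / "viability.tsv", sep="\t", index=False)
print(f"wrote inputs to {OUT}")
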