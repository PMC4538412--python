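"""C/D-box feature analysis of the simulated snoRNA probe set.

Per-sequence motif and dinucleotide features, IQR length fences and
outliers, homogeneity of the long outliers by mean pairwise K2P distance
(on a mutational family seeded from the first outlier), and the D-box
multiplicity vs regulation-direction table.

Reads results/synthetic/, writes results/snorna_features.tsv and
results/snorna_report.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from fluoro_sncrna import snofeat
from fluoro_sncrna.pipeline import mutate_family

ROOT = Path(__file__).resolve().parent.parent / "results"
IN = ROOT / "synthetic"
SEED = 17

seqs = [snofeat.SnoRNASeq(id=r.id, sequence=str(r.seq))
        for r in SeqIO.parse(str(IN / "snorna_cd.fasta"), "fasta")]
reg = pd.read_csv(IN / "regulation.tsv", sep="\t")
by_id: dict[str, dict[str, str]] = {}
for _, row in reg.iterrows():
    by_id.setdefault(str(row["probe_id"]), {})[str(row["dose"])] = str(row["direction"])
for s in seqs:
    s.regulation = by_id.get(s.id)

bounds = snofeat.length_outlier_bounds([s.length for s in seqs])
records = snofeat.feature_records(seqs, bounds=bounds)
pd.DataFrame([{k: v for k, v in vars(r).items() if k != "regulation"} for r in records]).to_csv(
    ROOT / "snorna_features.tsv", sep="\t", index=False
)

outliers = snofeat.flag_length_outliers(seqs, bounds=bounds)
family = mutate_family(outliers[0], len(outliers), seed=SEED + 2)
k2p = snofeat.mean_pairwise_k2p(family)
summary = snofeat.dbox_regulation_summary(records, dose="8mg")
out_recs = [r for r in records if r.is_length_outlier]

print(f"length fences: lower={bounds.lower:.2f} nt, upper={bounds.upper:.2f} nt "
      f"(q25={bounds.q25}, q75={bounds.q75})")
print(f"{len(outliers)} length outliers; mean pairwise K2P over the outlier family: "
      f"{k2p.mean:.3f} ({k2p.n_pairs_used} pairs, {k2p.n_pairs_saturated} saturated)")
print(f"outliers with >=2 D boxes: {100 * summary.frac_down_multi:.0f}% down-regulated; "
      f"with <2 D boxes: {100 * summary.frac_down_single:.0f}% down-regulated")
print(f"outlier dinucleotides: mean UG {np.mean([r.ug_count for r in out_recs]):.1f} "
      f"vs mean CG {np.mean([r.cg_count for r in out_recs]):.1f}")

report = {
    "bounds": vars(bounds),
    "n_length_outliers": len(outliers),
    "mean_k2p": {"mean": k2p.mean, "n_pairs_used": k2p.n_pairs_used},
    "dbox_regulation": vars(summary),
}
(ROOT / "snorna_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
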