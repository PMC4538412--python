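"""Scan synthetic UTRs for canonical seed sites of miR-124 and miR-155.

UTRs are generated with two planted 8mer sites per miRNA; the scanner must
find exactly those (no G:U wobble, best site type per window).

Writes results/seed_sites.tsv.
"""

from pathlib import Path

import pandas as pd

from fluoro_sncrna import seedscan, synthio
from fluoro_sncrna.pipeline import MIRNAS

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 17

rows = []
for i, (mid, mseq) in enumerate(sorted(MIRNAS.items())):
    utr = synthio.gen_utr_with_sites(mseq, n_sites=2, length=400, seed=SEED + 5 + i)
    sites = seedscan.find_seed_sites(utr, mseq, mirna_id=mid, target_id=f"synthetic_utr_{mid}")
    print(f"{mid} (seed {seedscan.extract_seed(mseq)}): {len(sites)} sites "
          f"{[(s.site_start, s.site_type) for s in sites]}")
    rows.extend(vars(s) for s in sites)

pd.DataFrame(rows).to_csv(ROOT / "seed_sites.tsv", sep="\t", index=False)
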