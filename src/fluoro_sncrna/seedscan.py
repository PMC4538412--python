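"""Canonical miRNA seed-site scanning on UTR sequences.

The seed is miRNA nucleotides 2-8 (1-based from the 5' end). A canonical
site on the UTR (given 5'->3') is a Watson-Crick reverse complement of part
of the seed — no G:U wobble:

    6mer     reverse complement of positions 2-7
    7mer-m8  6mer plus a match to position 8 (extends the site's 5' end)
    7mer-A1  6mer plus an adenosine opposite position 1 (site's 3' end)
    8mer     both extensions

Each 6mer-core window is reported once with its most specific type;
overlapping windows are allowed. Coordinates are 0-based half-open on the
UTR as provided; orientation handling is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from fluoro_sncrna.snofeat import normalize_sequence

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def extract_seed(mirna: str) -> str:
    """The 7-nt seed region: miRNA positions 2-8, 1-based from the 5' end."""
    seq = normalize_sequence(mirna)
    if len(seq) < 8:
        raise ValueError(f"miRNA must be >= 8 nt to have a seed (got {len(seq)})")
    return seq[1:8]


@dataclass(frozen=True)
class SeedMatch:
    """One seed-complementary site on a UTR, 0-based half-open coordinates."""

    mirna_id: str
    target_id: str
    site_start: int
    site_end: int
    site_type: str
    paired_seed: str  # the UTR subsequence at [site_start, site_end)


def find_seed_sites(
    utr: str, mirna: str, mirna_id: str = "mirna", target_id: str = "utr"
) -> list[SeedMatch]:
    """All canonical seed sites of ``mirna`` on ``utr`` (5'->3').

    Anchored on 6mer-core matches (reverse complement of miRNA positions
    2-7); each core position is reported once with the maximal site type it
    supports.
    """
    u = normalize_sequence(utr)
    m = normalize_sequence(mirna)
    if len(m) < 8:
        raise ValueError(f"miRNA must be >= 8 nt (got {len(m)})")
    core = reverse_complement(m[1:7])  # pairs positions 2-7
    m8_base = _COMPLEMENT[m[7]]  # pairs position 8, at the site's 5' side
    out = []
    i = u.find(core)
    while i != -1:
        has_m8 = i > 0 and u[i - 1] == m8_base
        has_a1 = i + 6 < len(u) and u[i + 6] == "A"
        if has_m8 and has_a1:
            start, end, site_type = i - 1, i + 7, "8mer"
        elif has_m8:
            start, end, site_type = i - 1, i + 6, "7mer-m8"
        elif has_a1:
            start, end, site_type = i, i + 7, "7mer-A1"
        else:
            start, end, site_type = i, i + 6, "6mer"
        out.append(
            SeedMatch(
                mirna_id=mirna_id,
                target_id=target_id,
                site_start=start,
                site_end=end,
                site_type=site_type,
                paired_seed=u[start:end],
            )
        )
        i = u.find(core, i + 1)
    return out


def scan_many(
    mirnas: dict[str, str], utrs: dict[str, str]
) -> list[SeedMatch]:
    """Seed sites for every miRNA x UTR combination."""
    out = []
    for mid, mseq in mirnas.items():
        for tid, useq in utrs.items():
            out.extend(find_seed_sites(useq, mseq, mirna_id=mid, target_id=tid))
    return out
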