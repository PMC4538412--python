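"""C/D-box snoRNA sequence features.

C/D-box snoRNAs guide 2'-O-ribose methylation of other RNAs. Their two
hallmark motifs are the C box (UGAUGA), usually near the 5' end, and the
D box (CUGA), usually near the 3' end; internal copies of either can occur.
This module scans for those motifs, counts UG/CG dinucleotides, detects
length outliers by the interquartile-range (Tukey fence) rule

    lower = q25 - 1.5 * IQR,   upper = q75 + 1.5 * IQR,

and measures sequence homogeneity with the Kimura two-parameter distance

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q),

where P and Q are the transition (A<->G, C<->U) and transversion
proportions over aligned, gap-free columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

C_BOX = "UGAUGA"
D_BOX = "CUGA"

_RNA_BASES = frozenset("ACGU")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CU")


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions past the model's domain."""


def normalize_sequence(raw: str, allow_n: bool = False) -> str:
    """Uppercase, convert T to U, and validate the RNA alphabet.

    Parameters
    ----------
    raw:
        Nucleotide string, DNA or RNA alphabet, any case.
    allow_n:
        If True, ``N`` is accepted (it never matches a motif or
        dinucleotide window); otherwise any character outside ACGTU is
        rejected with its position.
    """
    if not raw:
        raise ValueError("empty sequence")
    seq = raw.upper().replace("T", "U")
    allowed = _RNA_BASES | ({"N"} if allow_n else set())
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(f"disallowed character {ch!r} at position {i}")
    return seq


@dataclass
class SnoRNASeq:
    """One snoRNA probe sequence with optional per-dose regulation calls."""

    id: str
    sequence: str
    regulation: dict[str, str] | None = None  # dose -> {"up", "down", "flat"}

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _seq_str(s: "SnoRNASeq | str") -> str:
    return s.sequence if isinstance(s, SnoRNASeq) else normalize_sequence(s)


@dataclass(frozen=True)
class BoxAnnotation:
    """A single C- or D-box occurrence, 0-based half-open coordinates."""

    box_type: str  # "C" or "D"
    motif: str
    start: int
    end: int
    position_class: str  # terminal_5p | terminal_3p | internal


def _find_all(seq: str, motif: str) -> list[int]:
    """All (overlapping) start positions of motif in seq."""
    hits, i = [], seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return hits


def scan_boxes(s: "SnoRNASeq | str", terminal_window: int = 15) -> list[BoxAnnotation]:
    """All C-box (UGAUGA) and D-box (CUGA) occurrences with positional class.

    Overlapping/adjacent occurrences are all reported. An occurrence starting
    within ``terminal_window`` nt of the 5' end is ``terminal_5p``; one ending
    within the window of the 3' end is ``terminal_3p`` (5' precedence if both
    windows apply); anything else is ``internal``.
    """
    seq = _seq_str(s)
    n = len(seq)
    out: list[BoxAnnotation] = []
    for box_type, motif in (("C", C_BOX), ("D", D_BOX)):
        for start in _find_all(seq, motif):
            end = start + len(motif)
            if start < terminal_window:
                cls = "terminal_5p"
            elif end > n - terminal_window:
                cls = "terminal_3p"
            else:
                cls = "internal"
            out.append(BoxAnnotation(box_type, motif, start, end, cls))
    out.sort(key=lambda a: (a.start, a.box_type))
    return out


def dinucleotide_counts(
    s: "SnoRNASeq | str", pairs: Sequence[str] = ("UG", "CG")
) -> dict[str, int]:
    """Overlapping step-1 window counts of each requested dinucleotide."""
    seq = _seq_str(s)
    if len(seq) < 2:
        warnings.warn("sequence shorter than 2 nt: all dinucleotide counts are 0")
        return {p: 0 for p in pairs}
    return {p: sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == p) for p in pairs}


@dataclass(frozen=True)
class LengthOutlierBounds:
    """Tukey-fence bounds on sequence length (nt)."""

    q25: float
    q75: float
    iqr: float
    lower: float
    upper: float


def bounds_from_quantiles(q25: float, q75: float) -> LengthOutlierBounds:
    """Apply the 1.5*IQR fence rule to given quartiles."""
    if q75 < q25:
        raise ValueError("q75 must be >= q25")
    iqr = q75 - q25
    return LengthOutlierBounds(q25, q75, iqr, q25 - 1.5 * iqr, q75 + 1.5 * iqr)


def length_outlier_bounds(
    lengths: Sequence[int], quantile_method: str = "linear"
) -> LengthOutlierBounds:
    """Quartiles of the length distribution and the 1.5*IQR fences.

    ``quantile_method`` is any estimator accepted by :func:`numpy.quantile`
    (default ``"linear"``, interpolation between order statistics); the
    estimator matters near the fences, so it is explicit and reported.
    """
    if len(lengths) < 4:
        raise ValueError("need at least 4 lengths to estimate quartiles")
    q25, q75 = np.quantile(np.asarray(lengths, dtype=float), [0.25, 0.75], method=quantile_method)
    return bounds_from_quantiles(float(q25), float(q75))


def flag_length_outliers(
    seqs: Sequence[SnoRNASeq],
    bounds: LengthOutlierBounds | None = None,
    side: str = "upper_only",
    threshold: float | None = None,
) -> list[SnoRNASeq]:
    """Sequences whose length falls outside the fences, input order preserved.

    With ``bounds``, an upper-side outlier has length strictly above
    ``bounds.upper``; with an explicit ``threshold`` the published usage is
    followed and length >= threshold qualifies. ``side="both_sides"`` also
    returns lengths below ``bounds.lower``.
    """
    if bounds is None and threshold is None:
        raise ValueError("provide bounds or an explicit threshold")
    if side not in ("upper_only", "both_sides"):
        raise ValueError(f"unknown side {side!r}")

    def is_outlier(L: int) -> bool:
        if threshold is not None:
            hi = L >= threshold
        else:
            hi = L > bounds.upper
        if side == "both_sides" and bounds is not None:
            return hi or L < bounds.lower
        return hi

    return [s for s in seqs if is_outlier(s.length)]


@dataclass(frozen=True)
class K2PResult:
    p_transitions: float
    q_transversions: float
    sites_compared: int
    distance: float


def _global_align(a: str, b: str) -> tuple[str, str]:
    # Pinned scores for reproducibility: match +1, mismatch -1, gap -2 (open=extend).
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def k2p_distance(a: "SnoRNASeq | str", b: "SnoRNASeq | str", aligner: str = "global") -> K2PResult:
    """Kimura two-parameter distance between two sequences.

    Unequal-length inputs (or ``aligner="global"``) are globally aligned
    first; gap columns are excluded. ``aligner="none"`` compares equal-length
    sequences position-wise.

    Raises
    ------
    SaturationError
        If 1-2P-Q <= 0 or 1-2Q <= 0, where the log formula is undefined.
    ValueError
        If no comparable (gap-free) columns remain.
    """
    sa, sb = _seq_str(a), _seq_str(b)
    if not sa or not sb:
        raise ValueError("empty sequence")
    if aligner == "global" or len(sa) != len(sb):
        if aligner == "none":
            raise ValueError("aligner='none' requires equal-length sequences")
        sa, sb = _global_align(sa, sb)
    transitions = transversions = n = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in _PURINES) == (y in _PURINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable columns after alignment")
    P, Q = transitions / n, transversions / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P, Q, n, d)


@dataclass(frozen=True)
class MeanK2PReport:
    mean: float
    n_pairs_used: int
    n_pairs_saturated: int


def mean_pairwise_k2p(seqs: Sequence[SnoRNASeq]) -> MeanK2PReport:
    """Mean K2P distance over all unordered pairs; saturated pairs excluded."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    dists, saturated = [], 0
    for a, b in itertools.combinations(seqs, 2):
        try:
            dists.append(k2p_distance(a, b).distance)
        except SaturationError:
            saturated += 1
    if not dists:
        raise SaturationError("all pairs saturated; mean K2P undefined")
    return MeanK2PReport(float(np.mean(dists)), len(dists), saturated)


@dataclass(frozen=True)
class FeatureRecord:
    """Per-sequence feature summary for the C/D-box analysis."""

    id: str
    length: int
    c_box_count: int
    d_box_count: int
    ug_count: int
    cg_count: int
    is_length_outlier: bool
    regulation: dict[str, str] | None = None


def feature_records(
    seqs: Sequence[SnoRNASeq],
    bounds: LengthOutlierBounds | None = None,
    terminal_window: int = 15,
) -> list[FeatureRecord]:
    """Motif, dinucleotide and outlier features for every sequence.

    If ``bounds`` is omitted, they are computed from the lengths of the
    given set (requires >= 4 sequences).
    """
    if bounds is None:
        bounds = length_outlier_bounds([s.length for s in seqs])
    out = []
    for s in seqs:
        boxes = scan_boxes(s, terminal_window=terminal_window)
        dinuc = dinucleotide_counts(s)
        out.append(
            FeatureRecord(
                id=s.id,
                length=s.length,
                c_box_count=sum(1 for b in boxes if b.box_type == "C"),
                d_box_count=sum(1 for b in boxes if b.box_type == "D"),
                ug_count=dinuc["UG"],
                cg_count=dinuc["CG"],
                is_length_outlier=s.length > bounds.upper,
                regulation=s.regulation,
            )
        )
    return out


@dataclass(frozen=True)
class DBoxRegulationSummary:
    """2x2 contingency of D-box multiplicity vs down-regulation, outliers only.

    Strata are d_box_count >= 2 vs < 2; the outcome is "down" vs anything
    else at the requested dose. Fractions are NaN for empty strata.
    """

    dose: str
    n_multi_down: int
    n_multi_other: int
    n_single_down: int
    n_single_other: int
    frac_down_multi: float
    frac_down_single: float


def dbox_regulation_summary(
    records: Iterable[FeatureRecord], dose: str
) -> DBoxRegulationSummary:
    """Cross-tabulate D-box multiplicity against regulation for length outliers."""
    outliers = [r for r in records if r.is_length_outlier]
    missing = [r.id for r in outliers if not r.regulation or dose not in r.regulation]
    if missing:
        raise ValueError(f"missing regulation calls at dose {dose!r} for: {', '.join(missing)}")
    if not outliers:
        warnings.warn("no length outliers: D-box/regulation table is all zeros")
        return DBoxRegulationSummary(dose, 0, 0, 0, 0, float("nan"), float("nan"))
    cells = {("multi", "down"): 0, ("multi", "other"): 0, ("single", "down"): 0, ("single", "other"): 0}
    for r in outliers:
        stratum = "multi" if r.d_box_count >= 2 else "single"
        outcome = "down" if r.regulation[dose] == "down" else "other"
        cells[(stratum, outcome)] += 1
    n_multi = cells[("multi", "down")] + cells[("multi", "other")]
    n_single = cells[("single", "down")] + cells[("single", "other")]
    return DBoxRegulationSummary(
        dose=dose,
        n_multi_down=cells[("multi", "down")],
        n_multi_other=cells[("multi", "other")],
        n_single_down=cells[("single", "down")],
        n_single_other=cells[("single", "other")],
        frac_down_multi=cells[("multi", "down")] / n_multi if n_multi else float("nan"),
        frac_down_single=cells[("single", "down")] / n_single if n_single else float("nan"),
    )
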