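"""Synthetic inputs with planted ground truth.

Every downstream stage (array screening, snoRNA features, qPCR, seed
scanning) is exercised on data this module generates: C/D-box snoRNA sets
with planted motif counts and length outliers, 3-group probe-intensity
matrices with planted differential probes, and Ct tables whose true signed
fold changes are known. All generators are seed-deterministic: identical
spec + seed gives byte-identical output.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from fluoro_sncrna import snofeat
from fluoro_sncrna.arraydx import ProbeMatrix
from fluoro_sncrna.snofeat import C_BOX, D_BOX, SnoRNASeq

_BASES = "ACGU"


@dataclass
class SnoRNAGenSpec:
    """Recipe for a synthetic C/D-box snoRNA probe set.

    Defaults mirror the probe set the analysis targets: a main length mode
    in [48, 112] nt plus long outliers in [114, 237] nt, one C box per
    sequence and 0-5 D boxes. ``ug_enrichment`` is the relative weight of G
    after U in the background chain (1.0 = uniform; >1 enriches UG
    dinucleotides, emulating the cytosine-deamination signature seen in
    fluoride-exposed cells).
    """

    n_core: int
    n_outliers: int
    core_length_range: tuple[int, int] = (48, 112)
    outlier_length_range: tuple[int, int] = (114, 237)
    c_box_count_per_seq: int = 1
    d_box_counts: Sequence[int] = ()
    ug_enrichment: float = 1.0
    seed: int = 0
    regulation_rule: str = "dbox"  # "dbox": >=2 D boxes -> down, else up; "none"

    def __post_init__(self) -> None:
        if self.n_core < 0 or self.n_outliers < 0:
            raise ValueError("sequence counts must be >= 0")
        for lo, hi in (self.core_length_range, self.outlier_length_range):
            if lo > hi:
                raise ValueError("length range lower bound exceeds upper bound")
            if lo < len(C_BOX):
                raise ValueError("length range lower bound below the longest motif (6)")
        c_lo, c_hi = self.core_length_range
        o_lo, o_hi = self.outlier_length_range
        if max(c_lo, o_lo) <= min(c_hi, o_hi):
            raise ValueError("core and outlier length ranges must be disjoint")
        if len(self.d_box_counts) != self.n_core + self.n_outliers:
            raise ValueError("d_box_counts must have one entry per sequence")
        if self.c_box_count_per_seq < 0 or any(d < 0 for d in self.d_box_counts):
            raise ValueError("motif counts must be >= 0")
        if self.ug_enrichment < 0:
            raise ValueError("ug_enrichment must be >= 0")


def _markov_background(rng: np.random.Generator, n: int, ug_weight: float) -> str:
    """Background bases: uniform ACGU with G upweighted after U."""
    if n <= 0:
        return ""
    after_u = np.array([1.0, 1.0, ug_weight, 1.0])
    after_u /= after_u.sum()
    out = []
    prev = None
    for _ in range(n):
        p = after_u if prev == "U" else None
        base = _BASES[rng.choice(4, p=p)]
        out.append(base)
        prev = base
    return "".join(out)


def _plant_one(
    rng: np.random.Generator, length: int, n_c: int, n_d: int, ug_weight: float
) -> str:
    """One sequence of given length with exactly n_c C boxes and n_d D boxes.

    Motifs are placed in random non-overlapping slots; background is drawn
    and the whole sequence re-scanned; on any accidental motif the
    background (not the slots) is redrawn. This makes the scanner itself
    the correctness oracle for planting.
    """
    motifs = [C_BOX] * n_c + [D_BOX] * n_d
    total_motif = sum(len(m) for m in motifs)
    if total_motif > length:
        raise ValueError(f"motifs ({total_motif} nt) cannot fit in length {length}")
    rng.shuffle(motifs)
    n_gaps = len(motifs) + 1
    background_len = length - total_motif
    for _ in range(2000):
        # stars-and-bars split of background across the gaps around motifs
        if n_gaps > 1:
            cuts = np.sort(rng.integers(0, background_len + 1, size=n_gaps - 1))
            gap_sizes = np.diff(np.concatenate(([0], cuts, [background_len])))
        else:
            gap_sizes = np.array([background_len])
        parts = []
        for i, g in enumerate(gap_sizes):
            parts.append(_markov_background(rng, int(g), ug_weight))
            if i < len(motifs):
                parts.append(motifs[i])
        seq = "".join(parts)
        boxes = snofeat.scan_boxes(seq)
        c_found = sum(1 for b in boxes if b.box_type == "C")
        d_found = sum(1 for b in boxes if b.box_type == "D")
        if c_found == n_c and d_found == n_d:
            return seq
    raise RuntimeError("could not plant motifs without accidental copies; spec too dense")


def gen_snorna_set(spec: SnoRNAGenSpec) -> list[SnoRNASeq]:
    """Generate the snoRNA set; planted motif counts survive a re-scan exactly."""
    rng = np.random.default_rng(spec.seed)
    seqs: list[SnoRNASeq] = []
    n_total = spec.n_core + spec.n_outliers
    for i in range(n_total):
        is_outlier = i >= spec.n_core
        lo, hi = spec.outlier_length_range if is_outlier else spec.core_length_range
        n_d = int(spec.d_box_counts[i])
        required = len(C_BOX) * spec.c_box_count_per_seq + len(D_BOX) * n_d
        if required > hi:
            raise ValueError(
                f"sequence {i}: motifs need {required} nt but range upper bound is {hi}"
            )
        if is_outlier:
            length = int(rng.integers(max(lo, required), hi + 1))
        else:
            # main length mode: clipped normal at the centre of the core range,
            # sd = 1/5 of its width, so the bulk is concentrated and the IQR
            # fences fall near the core range's upper end
            mu, sd = (lo + hi) / 2.0, (hi - lo) / 5.0
            length = int(np.clip(round(rng.normal(mu, sd)), max(lo, required), hi))
        seq = _plant_one(rng, length, spec.c_box_count_per_seq, n_d, spec.ug_enrichment)
        kind = "OUT" if is_outlier else "CORE"
        regulation = None
        if spec.regulation_rule == "dbox":
            direction = "down" if n_d >= 2 else "up"
            regulation = {"8mg": direction, "20mg": direction}
        seqs.append(SnoRNASeq(id=f"sno_{kind}_{i:03d}", sequence=seq, regulation=regulation))
    return seqs


def write_fasta(seqs: Sequence[SnoRNASeq], path, wrap: int = 80) -> None:
    """Plain FASTA, wrapped at ``wrap`` columns (byte-deterministic)."""
    with open(path, "w") as fh:
        fh.write(fasta_str(seqs, wrap=wrap))


def fasta_str(seqs: Sequence[SnoRNASeq], wrap: int = 80) -> str:
    buf = io.StringIO()
    for s in seqs:
        buf.write(f">{s.id}\n")
        for i in range(0, len(s.sequence), wrap):
            buf.write(s.sequence[i : i + wrap] + "\n")
    return buf.getvalue()


GROUP_LABELS = ("control", "dose_low", "dose_high")


@dataclass
class MatrixGenSpec:
    """Recipe for a 3-group probe-intensity matrix with planted DE probes.

    Intensities are drawn on the log2 scale (probe baselines uniform in
    [6, 12], Gaussian noise ``noise_sd``) and exponentiated, giving the
    log-normal character of array data. A ``de_fraction`` of probes is
    shifted by ``effect_log2`` (random sign per probe) in both treated
    groups.
    """

    n_probes: int
    group_sizes: Sequence[int] = (3, 3, 3)
    de_fraction: float = 0.1
    effect_log2: float = 2.0
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if len(self.group_sizes) != 3 or any(g < 1 for g in self.group_sizes):
            raise ValueError("group_sizes must be three counts, all >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def gen_probe_matrix(spec: MatrixGenSpec) -> tuple[ProbeMatrix, pd.DataFrame]:
    """Probe matrix (linear scale) plus the truth table of planted DE probes.

    The truth table has columns ``probe_id``, ``direction`` ("up"/"down"
    in treated vs control) and ``effect_log2`` (signed shift).
    """
    rng = np.random.default_rng(spec.seed)
    probe_ids = [f"probe_{i:05d}" for i in range(spec.n_probes)]
    sample_ids, groups = [], {}
    for label, size in zip(GROUP_LABELS, spec.group_sizes):
        for k in range(size):
            sid = f"{label}_{k + 1}"
            sample_ids.append(sid)
            groups[sid] = label
    baseline = rng.uniform(6.0, 12.0, size=spec.n_probes)
    log2 = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, len(sample_ids)))

    n_de = int(round(spec.n_probes * spec.de_fraction))
    de_idx = rng.choice(spec.n_probes, size=n_de, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_de)
    treated_cols = [j for j, sid in enumerate(sample_ids) if groups[sid] != "control"]
    for idx, sign in zip(de_idx, signs):
        log2[idx, treated_cols] += sign * spec.effect_log2

    values = pd.DataFrame(np.exp2(log2), index=probe_ids, columns=sample_ids)
    truth = pd.DataFrame(
        {
            "probe_id": [probe_ids[i] for i in de_idx],
            "direction": ["up" if s > 0 else "down" for s in signs],
            "effect_log2": signs * spec.effect_log2,
        }
    ).sort_values("probe_id", ignore_index=True)
    return ProbeMatrix(values=values, groups=groups, scale="linear"), truth


def write_matrix_tsv(matrix: ProbeMatrix, matrix_path, samples_path) -> None:
    """TSV matrix (first column probe_id) plus a sample sheet (sample_id, group)."""
    matrix.values.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample_id": list(matrix.values.columns), "group": [matrix.groups[s] for s in matrix.values.columns]}
    ).to_csv(samples_path, sep="\t", index=False)


@dataclass
class CtGenSpec:
    """Recipe for a qPCR Ct table with known true signed fold changes.

    ``true_fc_signed`` maps each target gene to its generating signed fold
    change (|fc| >= 1; negative = down-regulated, reported as -1/ratio).
    Reference genes are held constant across conditions up to noise.
    """

    genes: Sequence[str]
    reference_genes: Sequence[str]
    true_fc_signed: dict[str, float]
    replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("reference_genes must be non-empty")
        if set(self.reference_genes) & set(self.genes):
            raise ValueError("reference genes must be disjoint from target genes")
        if set(self.true_fc_signed) != set(self.genes):
            raise ValueError("true_fc_signed must cover exactly the target genes")
        if any(abs(v) < 1.0 for v in self.true_fc_signed.values()):
            raise ValueError("signed fold changes must satisfy |fc| >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _signed_to_ddct(fc_signed: float) -> float:
    linear = fc_signed if fc_signed >= 1 else -1.0 / fc_signed
    return -float(np.log2(linear))


def gen_ct_table(spec: CtGenSpec) -> pd.DataFrame:
    """Ct table (sample, condition, gene, replicate, ct), conditions control/treated.

    With ``noise_sd=0`` the ddCt stage recovers ``true_fc_signed`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    ref_base = {g: 19.0 + 0.5 * i for i, g in enumerate(spec.reference_genes)}
    gene_base = {g: 23.0 + 0.7 * i for i, g in enumerate(spec.genes)}
    for condition in ("control", "treated"):
        for gene in list(spec.reference_genes) + list(spec.genes):
            if gene in ref_base:
                ct_mean = ref_base[gene]
            else:
                ct_mean = gene_base[gene]
                if condition == "treated":
                    ct_mean += _signed_to_ddct(spec.true_fc_signed[gene])
            for r in range(1, spec.replicates + 1):
                ct = ct_mean + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
                rows.append((f"{condition}_{r}", condition, gene, r, float(ct)))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "replicate", "ct"])


def gen_utr_with_sites(mirna: str, n_sites: int = 2, length: int = 400, seed: int = 0) -> str:
    """Random UTR containing exactly ``n_sites`` 8mer seed sites for ``mirna``.

    The 8mer window (reverse complement of miRNA positions 2-8 followed by
    an A) is planted in random non-overlapping slots; the whole UTR is
    re-scanned with the seed scanner and the background redrawn until
    exactly ``n_sites`` sites are found, so the scanner is the planting
    oracle.
    """
    from fluoro_sncrna.seedscan import find_seed_sites, reverse_complement

    mirna = snofeat.normalize_sequence(mirna)
    site = reverse_complement(mirna[1:8]) + "A"
    if n_sites * len(site) > length:
        raise ValueError(f"{n_sites} sites of {len(site)} nt cannot fit in {length} nt")
    rng = np.random.default_rng(seed)
    background_len = length - n_sites * len(site)
    for _ in range(2000):
        if n_sites > 0:
            cuts = np.sort(rng.integers(0, background_len + 1, size=n_sites))
            gaps = np.diff(np.concatenate(([0], cuts, [background_len])))
        else:
            gaps = np.array([background_len])
        parts = []
        for i, g in enumerate(gaps):
            parts.append("".join(_BASES[b] for b in rng.integers(0, 4, size=int(g))))
            if i < n_sites:
                parts.append(site)
        utr = "".join(parts)
        found = find_seed_sites(utr, mirna)
        if len(found) == n_sites and all(s.site_type == "8mer" for s in found):
            return utr
    raise RuntimeError("could not plant seed sites without accidental copies")


def gen_viability_table(
    lc50: float = 40.0, doses: Sequence[float] = (10, 20, 40, 80, 160, 250), hill: float = 1.5
) -> pd.DataFrame:
    """Dose-viability table from a Hill curve with the given LC50 (mg/L)."""
    doses = np.asarray(doses, dtype=float)
    viability = 1.0 / (1.0 + (doses / lc50) ** hill)
    return pd.DataFrame({"dose_mg_per_l": doses, "viability": viability})
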