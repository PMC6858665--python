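"""Synthetic genome, annotation and expression generator with planted truth.

The generator emulates the statistical structure the downstream analyses
assume: a TE-rich toy genome whose superfamily composition mirrors the
genomic proportions of a maize-like TE landscape (LTR/Gypsy and LTR/Copia
dominating by length), protein-coding genes carrying a long planted ORF,
long non-coding RNAs (>= 200 nt, longest ORF < 100 aa by construction),
TE-derived lncRNAs transcribed from within TE intervals, and a
negative-binomial count matrix with planted differential expression,
latent-factor co-expression modules, designated hub transcripts and
cis-coupled lncRNA/nearest-gene pairs.

All randomness flows through a single ``numpy`` generator seeded from
``SimulationConfig.seed``; two runs with the same config produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    TEAnnotation,
    TranscriptModel,
)
from . import io as tio

STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

#: Share of TE bases per superfamily in the simulated genome; mirrors the
#: genomic length proportions of the maize TE landscape (Gypsy ~0.596,
#: Copia ~0.324, DNA superfamilies ~0.06 in total, the rest minor).
DEFAULT_TE_WEIGHTS: dict[str, float] = {
    "LTR/Gypsy": 0.5964,
    "LTR/Copia": 0.3239,
    "LTR/Cassandra": 0.0010,
    "LINE/L1": 0.0096,
    "LINE/RTE-BovB": 0.0014,
    "SINE": 0.0002,
    "DNA/CMC-EnSpm": 0.0333,
    "DNA/hAT-Ac": 0.0073,
    "DNA/hAT-Tag1": 0.0008,
    "DNA/hAT-Tip100": 0.0014,
    "DNA/MULE-MuDR": 0.0093,
    "DNA/PIF-Harbinger": 0.0064,
    "DNA/TcMar-Stowaway": 0.0008,
    "DNA": 0.0003,
    "Helitron": 0.0078,
    "Unclassified": 0.0002,
}

#: Element length ranges (bp) per superfamily group prefix.
_TE_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "LTR/Cassandra": (400, 1200),
    "LTR": (4000, 12000),
    "LINE": (2000, 6000),
    "SINE": (150, 400),
    "DNA": (500, 3000),
    "Helitron": (1000, 6000),
    "Unclassified": (400, 2000),
}

DEFAULT_GROUPS: list[tuple[str, str, bool]] = [
    ("control", "V3", True),
    ("heat", "V3", False),
    ("cold", "V3", False),
    ("control", "V4", True),
    ("heat", "V4", False),
    ("cold", "V4", False),
    ("control", "V6", True),
    ("heat", "V6", False),
    ("cold", "V6", False),
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults are sized for desk scale."""

    seed: int = 0
    genome_length: int = 2_000_000
    chrom: str = "chr1"
    n_genes: int = 200
    n_lncRNA: int = 150
    te_superfamily_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TE_WEIGHTS)
    )
    te_total_fraction: float = 0.30
    frac_te_derived: float = 0.65
    frac_intronic: float = 0.10
    te_lnc_dna_bias: float = 2.0
    margin: int = 200
    groups: list[tuple[str, str, bool]] = field(
        default_factory=lambda: list(DEFAULT_GROUPS)
    )
    n_samples_per_group: int = 4
    n_total_rna_samples: int = 2
    frac_total_rna_only: float = 0.40
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    de_shared_fraction: float = 0.30
    nb_dispersion: float = 0.1
    n_modules: int = 3
    module_size: int = 30
    module_cor: float = 0.9
    trait_strength: float = 0.7
    n_hubs_per_module: int = 2
    hub_cor: float = 0.98
    n_cis_pairs: int = 0
    cis_cor: float = 0.5
    cis_lfc_sd: float = 2.0
    cis_min_fpkm: float = 10.0
    base_fpkm: dict[str, float] = field(
        default_factory=lambda: {"coding": 12.0, "lncRNA": 4.0, "TE_lncRNA": 2.0}
    )
    fpkm_sigma: float = 0.8
    min_detectable_fpkm: float = 0.8
    library_size: float = 2e6
    library_size_sigma: float = 0.15

    def __post_init__(self) -> None:
        for name in ("frac_te_derived", "frac_intronic", "frac_total_rna_only",
                     "de_fraction", "de_shared_fraction", "te_total_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        wsum = sum(self.te_superfamily_weights.values())
        if wsum > 1.0 + 1e-3:
            raise ValueError(f"te_superfamily_weights sum to {wsum:.3f} > 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted truth used as the oracle for every downstream stage."""

    true_class: dict[str, str] = field(default_factory=dict)
    te_superfamily: dict[str, str] = field(default_factory=dict)
    polyA_minus_ids: list[str] = field(default_factory=list)
    intronic_ids: list[str] = field(default_factory=list)
    true_de: dict[str, dict[str, float]] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    hub_ids: list[str] = field(default_factory=list)
    cis_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["cis_pairs"] = [tuple(p) for p in payload.get("cis_pairs", [])]
        return cls(**payload)


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def random_noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """A random nucleotide string of ``length`` whose longest ORF is < 100 aa.

    Rejection-samples uniform sequences; if a draw keeps failing, strips
    every ``ATG`` (no start codon, no ORF), which always terminates.
    """
    from .discovery import find_orfs

    if length < 1:
        raise ValueError("length must be positive")
    for _ in range(40):
        seq = _to_str(_rand_seq(rng, length))
        if find_orfs(seq, min_aa=1).longest_orf_aa < 100:
            return seq
    return seq.replace("ATG", "ATC")


def _coding_sequence(rng: np.random.Generator, length: int, min_aa: int = 150) -> str:
    """Random sequence of ``length`` with a planted ORF of >= ``min_aa`` aa."""
    max_aa = (length - 6) // 3 - 1
    if max_aa < min_aa:
        raise ValueError(f"length {length} too short for a {min_aa} aa ORF")
    aa = int(rng.integers(min_aa, min(450, max_aa) + 1))
    orf_nt = 3 * aa + 3
    pos = int(rng.integers(0, length - orf_nt + 1))
    codes = _rand_seq(rng, length)
    seq = list(_to_str(codes))
    orf = "ATG" + "".join(
        _NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=aa - 1)
    ) + STOP_CODONS[int(rng.integers(0, 3))]
    seq[pos:pos + orf_nt] = orf
    return "".join(seq)


def _draw_te_elements(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, str]]:
    """(length, superfamily) pieces whose per-family totals hit the weights."""
    te_target = cfg.te_total_fraction * cfg.genome_length
    pieces: list[tuple[int, str]] = []
    wsum = sum(cfg.te_superfamily_weights.values())
    for fam in sorted(cfg.te_superfamily_weights):
        weight = cfg.te_superfamily_weights[fam] / wsum
        target = weight * te_target
        key = fam if fam in _TE_LENGTH_RANGES else fam.split("/")[0]
        lo, hi = _TE_LENGTH_RANGES.get(key, (400, 2000))
        placed = 0
        while target - placed >= 150:
            n = int(rng.integers(lo, hi + 1))
            n = min(n, int(target - placed))
            if n < 150:
                break
            pieces.append((n, fam))
            placed += n
    return pieces


def _gene_structures(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[tuple[list[int], list[int]]]:
    """Per gene: (exon lengths, intron lengths), spliced length >= 560."""
    out = []
    for _ in range(cfg.n_genes):
        n_exons = int(rng.integers(2, 6))
        exons = [int(rng.integers(200, 601)) for _ in range(n_exons)]
        while sum(exons) < 560:
            exons[int(rng.integers(0, n_exons))] += 100
        introns = [int(rng.integers(300, 1501)) for _ in range(n_exons - 1)]
        out.append((exons, introns))
    return out


def simulate_genome_and_annotations(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GeneAnnotation, TEAnnotation, dict]:
    """Lay out TEs, genes and lncRNA loci on one chromosome.

    Returns the genome as a mutable uint8 base-code array (use
    :func:`genome_to_fasta` to materialise it), the gene and TE annotations,
    and a layout dict consumed by :func:`simulate_transcripts`.

    Raises a sizing error when the requested features cannot be packed into
    ``genome_length``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    te_pieces = _draw_te_elements(cfg, rng)
    genes = _gene_structures(cfg, rng)

    n_te_lnc = round(cfg.frac_te_derived * cfg.n_lncRNA)
    n_free_lnc = cfg.n_lncRNA - n_te_lnc
    n_intronic = round(cfg.frac_intronic * n_free_lnc)
    n_intergenic = n_free_lnc - n_intronic
    lnc_lengths = np.clip(
        np.round(rng.lognormal(math.log(400), 0.6, size=cfg.n_lncRNA)).astype(int),
        200,
        3000,
    )

    blocks: list[tuple[str, int, int]] = []  # (kind, length, index)
    for i, (length, _fam) in enumerate(te_pieces):
        blocks.append(("te", length, i))
    for i, (exons, introns) in enumerate(genes):
        blocks.append(("gene", sum(exons) + sum(introns), i))
    for i in range(n_intergenic):
        blocks.append(("lnc", int(lnc_lengths[i]), i))

    total = sum(b[1] for b in blocks) + cfg.margin * (len(blocks) + 1)
    if total > cfg.genome_length:
        raise ValueError(
            f"cannot pack {total} bp of features+margins into a "
            f"{cfg.genome_length} bp genome; increase genome_length"
        )
    order = rng.permutation(len(blocks))
    slack = cfg.genome_length - total
    gaps = rng.multinomial(slack, np.full(len(blocks) + 1, 1 / (len(blocks) + 1)))

    genome = _rand_seq(rng, cfg.genome_length)
    te_records: list[tuple[GenomicInterval, str]] = []
    gene_objs: list[Gene] = []
    lnc_loci: list[GenomicInterval] = []  # intergenic non-TE lncRNA loci
    pos = 0
    for k, bi in enumerate(order):
        kind, length, idx = blocks[bi]
        pos += cfg.margin + int(gaps[k])
        start = pos
        if kind == "te":
            te_records.append(
                (GenomicInterval(cfg.chrom, start, start + length), te_pieces[idx][1])
            )
        elif kind == "gene":
            exons, introns = genes[idx]
            exon_ivs = []
            p = start
            for j, el in enumerate(exons):
                exon_ivs.append(GenomicInterval(cfg.chrom, p, p + el, "+"))
                p += el
                if j < len(introns):
                    p += introns[j]
            gene_objs.append(
                Gene(
                    f"gene{idx + 1:04d}",
                    GenomicInterval(cfg.chrom, start, start + length, "+"),
                    exon_ivs,
                )
            )
        else:
            lnc_loci.append(GenomicInterval(cfg.chrom, start, start + length, "+"))
        pos += length
    te_records.sort(key=lambda r: r[0].start)
    gene_objs.sort(key=lambda g: g.span.start)
    lnc_loci.sort(key=lambda iv: iv.start)

    layout = {
        "lnc_loci": lnc_loci,
        "lnc_lengths": lnc_lengths,
        "n_te_lnc": n_te_lnc,
        "n_intronic": n_intronic,
        "n_intergenic": n_intergenic,
    }
    return genome, GeneAnnotation(gene_objs), TEAnnotation(te_records), layout


def _extract(genome: np.ndarray, exons: list[GenomicInterval]) -> str:
    return "".join(_to_str(genome[e.start:e.end]) for e in exons)


def _plant(genome: np.ndarray, exons: list[GenomicInterval], seq: str) -> None:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[codes]
    off = 0
    for e in exons:
        genome[e.start:e.end] = codes[off:off + len(e)]
        off += len(e)


def simulate_transcripts(
    cfg: SimulationConfig,
    genome: np.ndarray,
    ann: GeneAnnotation,
    te: TEAnnotation,
    layout: dict,
    rng: np.random.Generator,
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Plant coding, lncRNA, intronic-lncRNA and TE-lncRNA transcripts.

    Coding transcripts reuse their gene's exon structure and carry an ORF of
    >= 150 aa; every lncRNA is >= 200 nt with longest ORF < 100 aa
    (rejection-sampled); TE-lncRNAs are sub-intervals of TE elements with at
    most a ~10 % overhang, hence >= 90 % of their length is TE-covered.
    """
    truth = GroundTruth()
    transcripts: list[TranscriptModel] = []

    for gene in ann.genes:
        tid = f"t_{gene.gene_id}"
        seq = _coding_sequence(rng, sum(len(e) for e in gene.exons))
        _plant(genome, gene.exons, seq)
        transcripts.append(TranscriptModel(tid, gene.gene_id, list(gene.exons), seq))
        truth.true_class[tid] = "coding"

    lnc_lengths = layout["lnc_lengths"]
    n_idx = 0

    # intergenic, TE-free lncRNAs
    for iv in layout["lnc_loci"]:
        tid = f"lnc{n_idx + 1:04d}"
        seq = random_noncoding_sequence(rng, len(iv))
        _plant(genome, [iv], seq)
        transcripts.append(TranscriptModel(tid, tid, [iv], seq))
        truth.true_class[tid] = "lncRNA"
        n_idx += 1

    # intronic lncRNAs: fully inside a sufficiently long intron
    introns = [
        (g, intron)
        for g in ann.genes
        for intron in g.introns
        if len(intron) >= 280
    ]
    rng.shuffle(introns)
    placed = 0
    for g, intron in introns:
        if placed >= layout["n_intronic"]:
            break
        want = int(lnc_lengths[layout["n_intergenic"] + placed])
        length = min(want, len(intron) - 80)
        if length < 200:
            continue
        start = intron.start + 40
        iv = GenomicInterval(cfg.chrom, start, start + length, "+")
        tid = f"lnc{n_idx + 1:04d}"
        seq = random_noncoding_sequence(rng, length)
        _plant(genome, [iv], seq)
        transcripts.append(TranscriptModel(tid, tid, [iv], seq))
        truth.true_class[tid] = "lncRNA"
        truth.intronic_ids.append(tid)
        n_idx += 1
        placed += 1
    if placed < layout["n_intronic"]:
        raise ValueError(
            "not enough long introns to host intronic lncRNAs; "
            "increase n_genes or lower frac_intronic"
        )

    # TE-derived lncRNAs: carved out of TE elements.  Family targets are
    # base-pair shares: genomic share times te_lnc_dna_bias for DNA
    # superfamilies; each lncRNA goes to the family with the largest bp
    # deficit, which keeps the realized composition on target even though
    # short (DNA) elements truncate slices.
    elements = [(iv, fam) for iv, fam in te.records if len(iv) >= 260]
    genome_bp = te.total_bp_by_superfamily()
    fam_names = sorted({fam for _iv, fam in elements})
    total_g = sum(genome_bp.values())
    target_w = {
        f: genome_bp[f] / total_g
        * (cfg.te_lnc_dna_bias if f.startswith("DNA") else 1.0)
        for f in fam_names
    }
    wsum = sum(target_w.values())
    target_w = {f: w / wsum for f, w in target_w.items()}
    by_family: dict[str, list[int]] = {}
    for ei, (_iv, fam) in enumerate(elements):
        by_family.setdefault(fam, []).append(ei)
    assigned_bp = {f: 0 for f in fam_names}
    cursors = {i: el[0].start for i, el in enumerate(elements)}
    n_te_lnc = layout["n_te_lnc"]
    made = 0
    attempts = 0
    while made < n_te_lnc:
        attempts += 1
        if attempts > 50 * max(1, n_te_lnc):
            raise ValueError(
                "could not place all TE-derived lncRNAs; increase genome_length "
                "or te_total_fraction"
            )
        want = int(np.clip(lnc_lengths[layout["n_intergenic"] + placed + made], 200, 1500))
        total_assigned = sum(assigned_bp.values())
        ranked = sorted(
            fam_names,
            key=lambda f: -(target_w[f] * (total_assigned + want) - assigned_bp[f]),
        )
        ei = None
        for f in ranked:
            open_elems = [
                e for e in by_family.get(f, [])
                if elements[e][0].end - cursors[e] >= 200
            ]
            if open_elems:
                frees = np.array(
                    [elements[e][0].end - cursors[e] for e in open_elems], dtype=float
                )
                ei = int(open_elems[int(rng.choice(len(open_elems), p=frees / frees.sum()))])
                break
        if ei is None:
            raise ValueError(
                "all TE elements exhausted; increase te_total_fraction or genome_length"
            )
        iv, fam = elements[ei]
        free = iv.end - cursors[ei]
        length = min(want, free)
        start = cursors[ei]
        end = start + length
        # occasional small overhang past the element edge (still >= 90% inside)
        if end == iv.end and rng.random() < 0.3:
            over = int(min(90, length // 10))
            end += over
            length += over
        cursors[ei] = end + 20
        assigned_bp[fam] += length
        lnc_iv = GenomicInterval(cfg.chrom, start, end, "+")
        tid = f"lnc{n_idx + 1:04d}"
        seq = random_noncoding_sequence(rng, length)
        _plant(genome, [lnc_iv], seq)
        transcripts.append(TranscriptModel(tid, tid, [lnc_iv], seq))
        truth.true_class[tid] = "TE_lncRNA"
        truth.te_superfamily[tid] = fam
        n_idx += 1
        made += 1

    lnc_ids = [t for t, c in truth.true_class.items() if c != "coding"]
    n_minus = round(cfg.frac_total_rna_only * len(lnc_ids))
    minus = rng.choice(len(lnc_ids), size=n_minus, replace=False)
    truth.polyA_minus_ids = sorted(lnc_ids[i] for i in minus)
    return transcripts, truth


@dataclass
class SampleSheet:
    """Per-sample metadata: library type, condition, stage, control flag."""

    frame: pd.DataFrame  # index sample_id; columns library_type, condition, stage, is_control

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)


def build_sample_sheet(cfg: SimulationConfig) -> SampleSheet:
    rows = []
    for cond, stage, is_control in cfg.groups:
        for r in range(1, cfg.n_samples_per_group + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_{stage}_r{r}",
                    "library_type": "polyA",
                    "condition": cond,
                    "stage": stage,
                    "is_control": is_control,
                }
            )
    ctrl = next((g for g in cfg.groups if g[2]), cfg.groups[0])
    for r in range(1, cfg.n_total_rna_samples + 1):
        rows.append(
            {
                "sample_id": f"total_{ctrl[0]}_{ctrl[1]}_r{r}",
                "library_type": "total",
                "condition": ctrl[0],
                "stage": ctrl[1],
                "is_control": ctrl[2],
            }
        )
    return SampleSheet(pd.DataFrame(rows).set_index("sample_id"))


def contrast_names(cfg: SimulationConfig) -> list[str]:
    """stress_stage contrasts for which a same-stage control group exists."""
    stages_with_control = {s for c, s, ic in cfg.groups if ic}
    return [
        f"{cond}_{stage}"
        for cond, stage, is_control in cfg.groups
        if not is_control and stage in stages_with_control
    ]


def simulate_counts(
    cfg: SimulationConfig,
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    ann: GeneAnnotation,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SampleSheet, GroundTruth]:
    """Negative-binomial counts with planted DE, modules, hubs and cis pairs.

    Counts are NB with mean mu and variance ``mu + alpha mu^2``.  Per-sample
    means are ``base_fpkm * length/1e3 * library_size/1e6`` scaled by the
    planted group effect (``2**log2FC``) and, for module members, by a shared
    latent log-scale factor calibrated to the target within-module Pearson
    correlation.  lncRNAs flagged as total-RNA-only get zero counts in every
    polyA+ sample.
    """
    sheet = build_sample_sheet(cfg)
    meta = sheet.frame
    tids = [t.transcript_id for t in transcripts]
    n_t, n_s = len(tids), len(meta)
    lengths = np.array([t.length for t in transcripts], dtype=float)

    # Planted transcripts emulate *assembled* transcripts, which exist only
    # because they had expression evidence; lncRNA base levels are therefore
    # floored at a detectability level, with a higher floor for total-RNA-only
    # lncRNAs that must clear the FPKM filter in just the two total libraries.
    minus_set = set(truth.polyA_minus_ids)
    base_fpkm = np.empty(n_t)
    for i, tid in enumerate(tids):
        cls = truth.true_class[tid]
        mu = cfg.base_fpkm[cls]
        floor = 0.0
        if cls != "coding":
            if tid in minus_set:
                # must be seen in one of only two total-RNA libraries: floor
                # the expected count there at ~4 fragments
                floor = max(2.0, 4.0e3 / (lengths[i] * cfg.library_size / 1e6))
            else:
                floor = cfg.min_detectable_fpkm
        draw = rng.lognormal(math.log(mu) - cfg.fpkm_sigma**2 / 2, cfg.fpkm_sigma)
        for _ in range(200):
            if draw >= floor:
                break
            draw = rng.lognormal(math.log(mu) - cfg.fpkm_sigma**2 / 2, cfg.fpkm_sigma)
        base_fpkm[i] = max(draw, floor)
    lib_sizes = rng.lognormal(
        math.log(cfg.library_size) - cfg.library_size_sigma**2 / 2,
        cfg.library_size_sigma,
        size=n_s,
    )

    # --- planted co-expression modules ------------------------------------
    # (planted before DE so stress shifts never land on module members and
    # dilute the latent factor)
    alpha = np.full(n_t, cfg.nb_dispersion)
    module_mult = np.ones((n_t, n_s))
    member_set: set[int] = set()
    if cfg.n_modules > 0:
        exp_count = base_fpkm * lengths / 1e3 * cfg.library_size / 1e6
        eligible = [
            i for i, tid in enumerate(tids)
            if tid not in set(truth.polyA_minus_ids) and exp_count[i] >= 2.0
        ]
        need = cfg.n_modules * cfg.module_size
        if need > len(eligible):
            raise ValueError("not enough transcripts for the requested modules")
        member_idx = rng.choice(eligible, size=need, replace=False)
        member_set = set(int(i) for i in member_idx)
        stress_groups = [
            (c, s) for c, s, ic in cfg.groups if not ic
        ] or [(cfg.groups[0][0], cfg.groups[0][1])]
        for m in range(cfg.n_modules):
            members = member_idx[m * cfg.module_size:(m + 1) * cfg.module_size]
            cond, stage = stress_groups[m % len(stress_groups)]
            indicator = (
                (meta["condition"] == cond).to_numpy()
                & (meta["stage"] == stage).to_numpy()
            ).astype(float)
            ind = (indicator - indicator.mean()) / indicator.std()
            eps = rng.standard_normal(n_s)
            z = cfg.trait_strength * ind + math.sqrt(1 - cfg.trait_strength**2) * eps
            # Per-member latent loading calibrated so each member's share of
            # variance from the shared factor equals module_cor (hence any
            # member pair correlates at ~module_cor on the log scale);
            # the designated hubs — the most highly expressed members — are
            # coupled at hub_cor, which makes them the most connected
            # transcripts of their module by construction.
            by_expr = sorted(members, key=lambda ti: (-exp_count[ti], ti))
            hubs = set(by_expr[: cfg.n_hubs_per_module])
            for ti in members:
                noise_var = cfg.nb_dispersion + 1.0 / max(exp_count[ti], 1.0)
                target = cfg.hub_cor if ti in hubs else cfg.module_cor
                lam = min(math.sqrt(target / (1 - target) * noise_var), 2.5)
                module_mult[ti, :] = np.exp(lam * z)
                truth.module_labels[tids[ti]] = m + 1
            for ti in by_expr[: cfg.n_hubs_per_module]:
                truth.hub_ids.append(tids[ti])

    # --- cis-coupled lncRNA / nearest-gene pairs --------------------------
    # (planted before DE, and avoiding module members on either side, so the
    # only systematic signal a pair shares is the planted cis effect)
    from .downstream import nearest_gene

    contrasts = contrast_names(cfg)
    lfc = np.zeros((n_t, n_s))
    cis_idx: set[int] = set()
    if cfg.n_cis_pairs > 0:
        member_tids = {tids[i] for i in member_set}
        free_lnc = [
            t for t in transcripts
            if truth.true_class[t.transcript_id] == "lncRNA"
            and t.transcript_id not in truth.intronic_ids
            and t.transcript_id not in member_tids
            and t.transcript_id not in minus_set  # must be visible in polyA
        ]
        if cfg.n_cis_pairs > len(free_lnc):
            raise ValueError("n_cis_pairs exceeds available intergenic lncRNAs")
        order = rng.permutation(len(free_lnc))
        tid_index = {tid: i for i, tid in enumerate(tids)}
        used_genes: set[str] = set()
        chosen_pairs = []
        for pi in order:
            if len(chosen_pairs) >= cfg.n_cis_pairs:
                break
            lnc = free_lnc[pi]
            link = nearest_gene(lnc.span, ann)
            gene_tid = f"t_{link.gene_id}"
            # one lncRNA per gene (a shared nearest gene would receive two
            # independent planted effects), and no module-member genes (their
            # latent-factor structure would swamp the cis effect)
            if gene_tid in used_genes or gene_tid in member_tids:
                continue
            used_genes.add(gene_tid)
            chosen_pairs.append((lnc, gene_tid))
        if len(chosen_pairs) < cfg.n_cis_pairs:
            raise ValueError(
                "could not find enough lncRNAs with distinct nearest genes; "
                "lower n_cis_pairs or raise n_genes"
            )
        for lnc, gene_tid in chosen_pairs:
            truth.cis_pairs.append((lnc.transcript_id, gene_tid))
            # cis pairs emulate DE-detected lncRNAs, which are necessarily
            # expressed well enough to be testable
            li = tid_index[lnc.transcript_id]
            base_fpkm[li] = max(base_fpkm[li], cfg.cis_min_fpkm)
            cis_idx.update((li, tid_index[gene_tid]))
            for cname in contrasts:
                cond, stage = cname.rsplit("_", 1)
                cols = np.flatnonzero(
                    (meta["condition"] == cond).to_numpy()
                    & (meta["stage"] == stage).to_numpy()
                )
                z1, z2 = rng.standard_normal(2)
                g_eff = cfg.cis_lfc_sd * z1
                l_eff = cfg.cis_lfc_sd * (
                    cfg.cis_cor * z1 + math.sqrt(1 - cfg.cis_cor**2) * z2
                )
                lfc[tid_index[gene_tid], cols] += g_eff
                lfc[tid_index[lnc.transcript_id], cols] += l_eff

    # --- planted DE -------------------------------------------------------
    # (pool excludes module members and cis transcripts, which carry their
    # own planted effects, and total-RNA-only lncRNAs, whose shifts could
    # never be observed in the polyA-based contrasts)
    n_de = round(cfg.de_fraction * n_t)
    minus_idx = {i for i, tid in enumerate(tids) if tid in minus_set}
    idx_all = np.array(sorted(set(range(n_t)) - member_set - cis_idx - minus_idx))
    first_set: np.ndarray | None = None
    for cname in contrasts:
        truth.true_de[cname] = {}
        if n_de == 0:
            continue
        if first_set is None:
            chosen = rng.choice(idx_all, size=n_de, replace=False)
            first_set = chosen
        else:
            n_shared = round(cfg.de_shared_fraction * n_de)
            shared = rng.choice(first_set, size=min(n_shared, len(first_set)), replace=False)
            rest_pool = np.setdiff1d(idx_all, first_set)
            fresh = rng.choice(rest_pool, size=n_de - len(shared), replace=False)
            chosen = np.concatenate([shared, fresh])
        cond, stage = cname.rsplit("_", 1)
        cols = np.flatnonzero(
            (meta["condition"] == cond).to_numpy() & (meta["stage"] == stage).to_numpy()
        )
        for ti in chosen:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            eff = sign * cfg.de_log2fc
            lfc[ti, cols] += eff
            truth.true_de[cname][tids[ti]] = float(eff)

    # --- draw counts -------------------------------------------------------
    mu = (
        base_fpkm[:, None]
        * (lengths[:, None] / 1e3)
        * (lib_sizes[None, :] / 1e6)
        * np.exp2(lfc)
        * module_mult
    )
    r = 1.0 / alpha[:, None]
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)

    polyA_cols = np.flatnonzero((meta["library_type"] == "polyA").to_numpy())
    minus_rows = [i for i, tid in enumerate(tids) if tid in set(truth.polyA_minus_ids)]
    counts[np.ix_(minus_rows, polyA_cols)] = 0

    frame = pd.DataFrame(counts, index=tids, columns=meta.index)
    return frame, sheet, truth


def genome_to_fasta(genome: np.ndarray, chrom: str) -> dict[str, str]:
    return {chrom: _to_str(genome)}


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path | None = None):
    """Run the full generator; optionally write every output file.

    Returns ``(transcripts, annotation, te_annotation, counts, samples, truth,
    genome_fasta)``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome, ann, te, layout = simulate_genome_and_annotations(cfg, rng)
    transcripts, truth = simulate_transcripts(cfg, genome, ann, te, layout, rng)
    counts, sheet, truth = simulate_counts(cfg, transcripts, truth, ann, rng)
    fasta = genome_to_fasta(genome, cfg.chrom)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_fasta(fasta, outdir / "genome.fa")
        tio.write_gff3_genes(ann, outdir / "genes.gff3")
        tio.write_te_bed(te, outdir / "te.bed")
        tio.write_gtf(transcripts, outdir / "transcripts.gtf")
        tio.write_fasta(
            {t.transcript_id: t.sequence for t in transcripts},
            outdir / "transcripts.fa",
        )
        counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="transcript_id")
        sheet.frame.to_csv(outdir / "samples.tsv", sep="\t")
        truth.to_json(outdir / "truth.json")
        _write_evidence_tables(transcripts, truth, outdir, np.random.default_rng(cfg.seed + 1))
    return transcripts, ann, te, counts, sheet, truth, fasta


def _write_evidence_tables(
    transcripts: list[TranscriptModel],
    truth: GroundTruth,
    outdir: Path,
    rng: np.random.Generator,
) -> None:
    """Emulated external coding-potential and Pfam evidence, driven by truth."""
    rows_cpc, rows_cnci, rows_pfam = [], [], []
    for t in transcripts:
        coding = truth.true_class[t.transcript_id] == "coding"
        if coding:
            score = float(rng.uniform(1.0, 5.0))
            rows_cpc.append((t.transcript_id, score, "coding"))
            rows_cnci.append((t.transcript_id, "coding"))
            rows_pfam.append((t.transcript_id, float(10 ** rng.uniform(-60, -10))))
        else:
            score = float(rng.uniform(-5.0, -1.2))
            rows_cpc.append((t.transcript_id, score, "noncoding"))
            rows_cnci.append((t.transcript_id, "noncoding"))
    pd.DataFrame(rows_cpc, columns=["transcript_id", "score", "label"]).to_csv(
        outdir / "cpc2.tsv", sep="\t", index=False
    )
    pd.DataFrame(rows_cnci, columns=["transcript_id", "label"]).to_csv(
        outdir / "cnci.tsv", sep="\t", index=False
    )
    pd.DataFrame(rows_pfam, columns=["transcript_id", "best_evalue"]).to_csv(
        outdir / "pfam.tsv", sep="\t", index=False
    )
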