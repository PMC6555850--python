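"""Synthetic regulatory-genomics data with known ground truth.

The generator emulates the statistical structure of a paired
transcriptome + accessible-chromatin study of one target cell type against
several reference cell types: a random genome with annotated TSSs, a
target peak set with promoter peaks (within +/- 3 kb of TSS) and distal
peaks (out to 1 Mb), reference peak sets sharing a configurable fraction
of those peaks, PWMs whose consensus sites are planted into a subset of
peaks, and an FPKM expression table in which the target cell type's
expression is a noisy linear function of the TF regulatory scores computed
from the planted landscape::

    log2(FPKM + 1) = beta0 + x_g^T beta + Normal(0, noise_sd)

Every quantity needed to check downstream inference (planted sites, the
design matrix actually used, the coefficients, the designated enriched
genes and enriched peaks) is recorded in :class:`SyntheticTruth`.

A lighter matrix-level generator, :func:`simulate_promoter_hits`, draws
promoter hits (p-values, RPKMs, TSS distances) directly from the same
distributions without a genome, for regression-scale studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motifs as mo
from .expression import ExpressionTable
from .genomics import GeneModel, Peak, PeakSet, write_bed, write_gene_annotation
from .tfrs import PROMOTER_SCHEMES, PromoterHit, build_design_matrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output.

    Defaults mirror the structure of a cell-type comparison study:
    ~100 designated enriched genes out of 150, three reference cell types,
    just over half of the genes carrying a promoter accessible region, and
    peak sharing tuned so roughly 10% of target peaks are target-only.
    """

    n_genes: int = 150
    n_enriched_genes: int = 100
    n_tfs: int = 11
    n_references: int = 3
    chrom_length: int = 5_000_000
    chrom_name: str = "chrS"
    distal_max_bp: int = 1_000_000
    min_gene_spacing: int = 12_000
    promoter_dhs_prob: float = 0.55
    promoter_offset_sd: float = 1000.0
    distal_dhs_per_gene: float = 5.0
    peak_width_min: int = 150
    peak_width_max: int = 400
    motif_plant_prob: float = 0.3
    motif_length: int = 10
    shared_fraction: float = 0.55
    generating_scheme: str = "pval_dist"
    beta0: float = 2.0
    true_coefficients: list[float] | None = None
    noise_sd: float | None = None  # None: calibrated to target_r2
    target_r2: float = 0.7
    replicate_jitter_sd: float = 0.05
    n_replicates: int = 2
    enriched_fold: float = 8.0
    target_label: str = "target"
    seed: int = 0

    @property
    def reference_labels(self) -> list[str]:
        return [f"ref{i + 1}" for i in range(self.n_references)]

    def validate(self) -> None:
        for name in ("promoter_dhs_prob", "motif_plant_prob", "shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 2:
            raise ConfigurationError("n_genes must be >= 2")
        if not 0 < self.n_enriched_genes <= self.n_genes:
            raise ConfigurationError("n_enriched_genes must be in (0, n_genes]")
        if self.generating_scheme not in PROMOTER_SCHEMES:
            raise ConfigurationError(
                f"generating_scheme must be one of {PROMOTER_SCHEMES}"
            )
        if self.true_coefficients is not None and len(self.true_coefficients) != self.n_tfs:
            raise ConfigurationError(
                f"true_coefficients has length {len(self.true_coefficients)}, "
                f"expected n_tfs={self.n_tfs}"
            )
        lo, hi = self.distal_max_bp, self.chrom_length - self.distal_max_bp
        needed = (self.n_genes - 1) * self.min_gene_spacing + 1
        if hi - lo < needed:
            raise ConfigurationError(
                f"chrom_length={self.chrom_length} too small: genes need "
                f"{needed} bp between the +/-{self.distal_max_bp} bp margins"
            )
        if self.peak_width_min < self.motif_length:
            raise ConfigurationError("peak_width_min must be >= motif_length")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating one synthetic dataset."""

    generating_scheme: str
    planted_sites: dict[tuple[str, str], list[tuple[int, str]]] = field(default_factory=dict)
    promoter_peak_of_gene: dict[str, str] = field(default_factory=dict)
    enriched_gene_ids: list[str] = field(default_factory=list)
    enriched_dhs_names: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    tf_names: list[str] = field(default_factory=list)
    beta0: float = 0.0
    beta: np.ndarray | None = None
    noise_sd: float | None = None
    gene_tfrs_features: np.ndarray | None = None  # gene x TF design matrix X
    expression_noiseless: np.ndarray | None = None  # beta0 + X beta, log2 scale

    def to_json(self, path) -> None:
        obj = {
            "generating_scheme": self.generating_scheme,
            "planted_sites": {
                f"{tf}|{peak}": sites for (tf, peak), sites in self.planted_sites.items()
            },
            "promoter_peak_of_gene": self.promoter_peak_of_gene,
            "enriched_gene_ids": self.enriched_gene_ids,
            "enriched_dhs_names": self.enriched_dhs_names,
            "gene_ids": self.gene_ids,
            "tf_names": self.tf_names,
            "beta0": self.beta0,
            "beta": None if self.beta is None else [float(b) for b in self.beta],
            "noise_sd": self.noise_sd,
            "gene_tfrs_features": None
            if self.gene_tfrs_features is None
            else np.round(self.gene_tfrs_features, 12).tolist(),
            "expression_noiseless": None
            if self.expression_noiseless is None
            else np.round(self.expression_noiseless, 12).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            obj = json.load(fh)
        truth = cls(generating_scheme=obj["generating_scheme"])
        truth.planted_sites = {
            tuple(k.split("|")): [(int(o), s) for o, s in v]
            for k, v in obj["planted_sites"].items()
        }
        truth.promoter_peak_of_gene = obj["promoter_peak_of_gene"]
        truth.enriched_gene_ids = obj["enriched_gene_ids"]
        truth.enriched_dhs_names = obj["enriched_dhs_names"]
        truth.gene_ids = obj["gene_ids"]
        truth.tf_names = obj["tf_names"]
        truth.beta0 = obj["beta0"]
        truth.beta = None if obj["beta"] is None else np.array(obj["beta"])
        truth.noise_sd = obj["noise_sd"]
        if obj["gene_tfrs_features"] is not None:
            truth.gene_tfrs_features = np.array(obj["gene_tfrs_features"])
        if obj["expression_noiseless"] is not None:
            truth.expression_noiseless = np.array(obj["expression_noiseless"])
        return truth


def decode(codes: np.ndarray) -> str:
    """Integer base codes back to an ACGT string."""
    return _BASES[codes].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Stage 1: genome and annotation


def generate_genome(config: SimulationConfig) -> tuple[np.ndarray, list[GeneModel]]:
    """I.i.d. uniform-base genome plus gene models with distinct TSSs.

    TSSs keep ``min_gene_spacing`` bp between neighbours and stay
    ``distal_max_bp`` clear of the chromosome ends so every gene's distal
    window fits.  TF identities are assigned to a random subset of genes
    (ids ``TF01`` ...), so regulators have their own expression rows.
    """
    config.validate()
    rng = config._rng(0)
    genome = rng.integers(0, 4, size=config.chrom_length, dtype=np.int8)

    lo = config.distal_max_bp
    hi = config.chrom_length - config.distal_max_bp
    n_slots = (hi - lo) // config.min_gene_spacing
    if n_slots < config.n_genes:
        raise ConfigurationError(
            f"chromosome fits only {n_slots} gene slots, need {config.n_genes}"
        )
    slots = np.sort(rng.choice(n_slots, size=config.n_genes, replace=False))
    jitter = rng.integers(0, max(config.min_gene_spacing // 4, 1), size=config.n_genes)
    tss = lo + slots * config.min_gene_spacing + jitter
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)

    width = len(str(config.n_genes))
    ids = [f"TF{k + 1:02d}" for k in range(config.n_tfs)] + [
        f"g{k:0{width}d}" for k in range(config.n_tfs, config.n_genes)
    ]
    ids = [ids[i] for i in rng.permutation(config.n_genes)]
    genes = [
        GeneModel(gene_id=ids[i], chrom=config.chrom_name, strand=str(strands[i]),
                  tss=int(tss[i]))
        for i in range(config.n_genes)
    ]
    return genome, genes


def generate_pwms(config: SimulationConfig) -> list[mo.PWM]:
    """Informative random PWMs, one per TF; per-column consensus
    probability drawn in [0.75, 0.95]."""
    rng = config._rng(1)
    pwms = []
    for k in range(config.n_tfs):
        matrix = np.empty((4, config.motif_length))
        for j in range(config.motif_length):
            top = rng.integers(0, 4)
            p_top = rng.uniform(0.75, 0.95)
            matrix[:, j] = (1.0 - p_top) / 3.0
            matrix[top, j] = p_top
        pwms.append(mo.PWM(tf_name=f"TF{k + 1:02d}", matrix=matrix, pseudocount=0.0))
    return pwms


# ---------------------------------------------------------------------------
# Stage 2: peaks, reference sets, motif planting


@dataclass
class _Candidate:
    start: int
    end: int
    gene_id: str
    kind: str  # 'promoter' | 'distal'
    signal: float
    q: float


def generate_peaks_and_motifs(
    config: SimulationConfig,
    genes: list[GeneModel],
    genome: np.ndarray,
) -> tuple[PeakSet, list[PeakSet], list[mo.PWM], SyntheticTruth, np.ndarray]:
    """Target and reference peak sets with planted consensus motif sites.

    Each gene gets a promoter peak with probability ``promoter_dhs_prob``
    (midpoint offset ~ Normal(0, promoter_offset_sd) within +/- 3 kb of the
    TSS) and Poisson(``distal_dhs_per_gene``) distal peaks with midpoints
    uniform in (3 kb, distal_max_bp].  Candidate peaks that would overlap
    an earlier-priority peak are dropped, so each set is disjoint.  Every
    reference set independently contains each target peak with probability
    ``shared_fraction`` plus its own target-avoiding peaks; target peaks in
    no reference set are the designated enriched peaks.  For each
    (TF, target peak) pair, with probability ``motif_plant_prob`` the TF's
    consensus is written into the genome at a random non-clashing offset
    (random strand) and recorded in the returned :class:`SyntheticTruth`.

    Returns (target set, reference sets, PWMs, truth, planted genome).
    """
    config.validate()
    rng = config._rng(2)
    pwms = generate_pwms(config)
    genome = genome.copy()

    candidates: list[_Candidate] = []

    def _signal_q() -> tuple[float, float]:
        return float(rng.lognormal(1.0, 0.7)), float(rng.uniform(1e-6, 0.049))

    for g in genes:
        if rng.random() < config.promoter_dhs_prob:
            w = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
            offset = int(np.clip(round(rng.normal(0.0, config.promoter_offset_sd)),
                                 -(2999 - w // 2), 2999 - w // 2))
            mid = g.tss + offset
            s, q = _signal_q()
            candidates.append(_Candidate(mid - w // 2, mid - w // 2 + w, g.gene_id,
                                         "promoter", s, q))
    for g in genes:
        for _ in range(rng.poisson(config.distal_dhs_per_gene)):
            w = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
            d = int(rng.integers(3001 + w, config.distal_max_bp + 1))
            side = 1 if rng.random() < 0.5 else -1
            mid = g.tss + side * d
            if mid - w // 2 < 0 or mid - w // 2 + w > config.chrom_length:
                continue
            s, q = _signal_q()
            candidates.append(_Candidate(mid - w // 2, mid - w // 2 + w, g.gene_id,
                                         "distal", s, q))

    # greedy non-overlap resolution; promoter candidates take priority
    accepted: list[_Candidate] = []
    occupied: list[tuple[int, int]] = []

    def _clashes(start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in occupied)

    for cand in candidates:  # promoter candidates listed first
        if not _clashes(cand.start, cand.end):
            accepted.append(cand)
            occupied.append((cand.start, cand.end))
    accepted.sort(key=lambda c: c.start)

    truth = SyntheticTruth(generating_scheme=config.generating_scheme)
    truth.gene_ids = [g.gene_id for g in genes]
    truth.tf_names = [p.tf_name for p in pwms]

    target_peaks: list[Peak] = []
    for i, cand in enumerate(accepted):
        name = f"peak_{i:05d}"
        target_peaks.append(
            Peak(chrom=config.chrom_name, start=cand.start, end=cand.end,
                 signal_rpkm=cand.signal, q_value=cand.q, name=name)
        )
        if cand.kind == "promoter" and cand.gene_id not in truth.promoter_peak_of_gene:
            truth.promoter_peak_of_gene[cand.gene_id] = name
    target = PeakSet(target_peaks, label=config.target_label)

    # reference sets: shared target peaks plus reference-specific peaks
    # placed clear of all target peaks (so target-only status is by design)
    references: list[PeakSet] = []
    shared_by_any = np.zeros(len(target_peaks), dtype=bool)
    for r, label in enumerate(config.reference_labels):
        shared = rng.random(len(target_peaks)) < config.shared_fraction
        shared_by_any |= shared
        ref_peaks = [
            Peak(p.chrom, p.start, p.end, float(rng.lognormal(1.0, 0.7)),
                 float(rng.uniform(1e-6, 0.049)), name=f"{label}_{p.name}")
            for p, keep in zip(target_peaks, shared) if keep
        ]
        n_own = rng.poisson(0.3 * max(len(target_peaks), 1))
        placed = 0
        attempts = 0
        own_occupied = [(p.start, p.end) for p in ref_peaks]
        while placed < n_own and attempts < 20 * n_own + 100:
            attempts += 1
            w = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
            start = int(rng.integers(0, config.chrom_length - w))
            if _clashes(start, start + w):
                continue  # never shadow a target peak
            if any(start < e and s < start + w for s, e in own_occupied):
                continue
            ref_peaks.append(
                Peak(config.chrom_name, start, start + w,
                     float(rng.lognormal(1.0, 0.7)), float(rng.uniform(1e-6, 0.049)),
                     name=f"{label}_own_{placed:05d}")
            )
            own_occupied.append((start, start + w))
            placed += 1
        references.append(PeakSet(ref_peaks, label=label))
    truth.enriched_dhs_names = [
        p.name for p, hit in zip(target_peaks, shared_by_any) if not hit
    ]

    # motif planting: consensus written into the genome, one record per site
    consensus_codes = {p.tf_name: mo.encode(p.consensus) for p in pwms}
    site_occupancy: dict[str, list[tuple[int, int]]] = {}
    L = config.motif_length
    for peak in target_peaks:
        taken = site_occupancy.setdefault(peak.name, [])
        for pwm in pwms:
            if rng.random() >= config.motif_plant_prob:
                continue
            for _ in range(4):  # few placement attempts, then give up
                offset = int(rng.integers(0, peak.width - L + 1))
                if any(offset < e and s < offset + L for s, e in taken):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                codes = consensus_codes[pwm.tf_name]
                if strand == "-":
                    codes = mo._COMPLEMENT[codes][::-1].astype(np.int8)
                genome[peak.start + offset : peak.start + offset + L] = codes
                taken.append((offset, offset + L))
                truth.planted_sites.setdefault((pwm.tf_name, peak.name), []).append(
                    (offset, strand)
                )
                break
    return target, references, pwms, truth, genome


# ---------------------------------------------------------------------------
# Stage 3: expression


def noise_sd_for_r2(signal: np.ndarray, r2: float) -> float:
    """Noise sd giving the requested fraction of explained variance."""
    var = float(np.var(signal))
    if var == 0.0:
        return 1.0
    return float(np.sqrt(var * (1.0 - r2) / r2))


def _resolve_beta(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.true_coefficients is not None:
        return np.asarray(config.true_coefficients, dtype=float)
    # default: ~60% of TFs act as activators with effect U(0.5, 1.5)
    active = rng.random(config.n_tfs) < 0.6
    beta = np.where(active, rng.uniform(0.5, 1.5, size=config.n_tfs), 0.0)
    return beta


def generate_expression(
    config: SimulationConfig,
    truth: SyntheticTruth,
    tfrs_features: np.ndarray,
    genes: list[GeneModel],
) -> ExpressionTable:
    """FPKM table for the target and reference cell types.

    Target log2(FPKM+1) = beta0 + X beta + Normal(0, noise_sd); replicates
    add Normal(0, replicate_jitter_sd) on the log scale and the inverse
    transform floors FPKM at 0.  A seeded subset of ``n_enriched_genes``
    genes is designated enriched: reference cell types express them at
    1/enriched_fold of the target mean; other genes keep the target mean.
    """
    rng = config._rng(3)
    X = np.asarray(tfrs_features, dtype=float)
    beta = truth.beta if truth.beta is not None else _resolve_beta(config, rng)
    if X.shape != (config.n_genes, config.n_tfs):
        raise ConfigurationError(
            f"design matrix shape {X.shape} != (n_genes, n_tfs) "
            f"= ({config.n_genes}, {config.n_tfs})"
        )
    if len(beta) != config.n_tfs:
        raise ConfigurationError(
            f"beta length {len(beta)} != n_tfs = {config.n_tfs}"
        )
    noiseless = config.beta0 + X @ beta
    noise_sd = (
        config.noise_sd
        if config.noise_sd is not None
        else noise_sd_for_r2(noiseless, config.target_r2)
    )
    y = noiseless + rng.normal(0.0, noise_sd, size=config.n_genes)

    enriched_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_enriched_genes, replace=False)
    )
    gene_ids = [g.gene_id for g in genes]

    truth.beta0 = config.beta0
    truth.beta = beta
    truth.noise_sd = float(noise_sd)
    truth.gene_tfrs_features = X
    truth.expression_noiseless = noiseless
    truth.enriched_gene_ids = [gene_ids[i] for i in enriched_idx]

    target_mean_fpkm = np.maximum(np.exp2(y) - 1.0, 0.0)
    ref_mean_fpkm = target_mean_fpkm.copy()
    mask = np.zeros(config.n_genes, dtype=bool)
    mask[enriched_idx] = True
    ref_mean_fpkm[mask] = target_mean_fpkm[mask] / config.enriched_fold

    columns: dict[str, np.ndarray] = {}

    def _replicates(label: str, mean_fpkm: np.ndarray) -> None:
        log_mean = np.log2(mean_fpkm + 1.0)
        for rep in range(1, config.n_replicates + 1):
            noisy = log_mean + rng.normal(0.0, config.replicate_jitter_sd,
                                          size=config.n_genes)
            columns[f"{label}.rep{rep}"] = np.maximum(np.exp2(noisy) - 1.0, 0.0)

    _replicates(config.target_label, target_mean_fpkm)
    for label in config.reference_labels:
        _replicates(label, ref_mean_fpkm)
    df = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    return ExpressionTable(df)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class SimulationResult:
    config: SimulationConfig
    genes: list[GeneModel]
    genome: np.ndarray
    target: PeakSet
    references: list[PeakSet]
    pwms: list[mo.PWM]
    truth: SyntheticTruth
    promoter_hits: list[PromoterHit]
    expression: ExpressionTable


def promoter_hits_from_landscape(
    genes: list[GeneModel],
    genome: np.ndarray,
    target: PeakSet,
    pwms: list[mo.PWM],
    promoter_bp: int = 3000,
    chunk_len: int = mo.DEFAULT_CHUNK_LEN,
) -> list[PromoterHit]:
    """Per-(TF, gene) promoter hits computed by the package's own scanner.

    The lognormal null for each PWM is fitted on 200-bp chunks tiled from
    the TSS +/- 3 kb windows of ALL genes; the per-gene p-value is the
    per-region enrichment p of the gene's promoter peak sequence.  The hit
    carries the peak's RPKM and its unsigned midpoint-to-TSS distance.
    """
    bg_regions = [
        decode(genome[max(g.tss - promoter_bp, 0): g.tss + promoter_bp])
        for g in genes
    ]
    pairs = promoter_peak_pairs(genes, target, promoter_bp)
    # score each distinct peak once per PWM, then fan out to genes
    peak_seqs = {p.name: decode(genome[p.start: p.end])
                 for _, p in pairs}
    hits: list[PromoterHit] = []
    for pwm in pwms:
        bg = mo.fit_background(bg_regions, pwm, chunk_len=chunk_len)
        names = sorted(peak_seqs)
        _, per_region = mo.enrich([peak_seqs[n] for n in names], pwm, bg,
                                  region_ids=names)
        p_by_name = {r.region_id: r.p_value for r in per_region}
        for g, peak in pairs:
            hits.append(
                PromoterHit(
                    tf_name=pwm.tf_name,
                    gene_id=g.gene_id,
                    p_value=p_by_name[peak.name],
                    rpkm_dhs=peak.signal_rpkm,
                    distance_bp=abs(peak.midpoint - g.tss),
                )
            )
    return hits


def promoter_peak_pairs(
    genes: list[GeneModel], target: PeakSet, promoter_bp: int = 3000
) -> list[tuple[GeneModel, Peak]]:
    """All (gene, peak) pairs where the peak overlaps the gene's
    TSS +/- promoter_bp window — a gene may own several promoter peaks."""
    pairs = []
    for g in genes:
        for p in target:
            if p.chrom == g.chrom and p.start < g.tss + promoter_bp \
                    and g.tss - promoter_bp < p.end:
                pairs.append((g, p))
    return pairs


def planted_promoter_targets(
    genes: list[GeneModel],
    target: PeakSet,
    truth: SyntheticTruth,
    tf_name: str,
    promoter_bp: int = 3000,
) -> set[str]:
    """Ground-truth target genes of a TF: genes with >= 1 promoter-window
    peak carrying a planted site of that TF."""
    planted_peaks = {
        peak for (tf, peak) in truth.planted_sites if tf == tf_name
    }
    return {
        g.gene_id
        for g, p in promoter_peak_pairs(genes, target, promoter_bp)
        if p.name in planted_peaks
    }


def simulate(config: SimulationConfig, outdir=None) -> SimulationResult:
    """Run the full generator and (optionally) write the dataset to disk.

    Files: genome.fa, genes.tsv, <target>.bed, <ref>.bed per reference,
    expression.tsv, pwms.jaspar, truth.json, config.json.  Identical
    configs give byte-identical files.
    """
    genome0, genes = generate_genome(config)
    target, references, pwms, truth, genome = generate_peaks_and_motifs(
        config, genes, genome0
    )
    hits = promoter_hits_from_landscape(genes, genome, target, pwms)
    X = build_design_matrix(
        hits, [g.gene_id for g in genes], [p.tf_name for p in pwms],
        config.generating_scheme,
    ).scores
    expression = generate_expression(config, truth, X, genes)

    result = SimulationResult(
        config=config, genes=genes, genome=genome, target=target,
        references=references, pwms=pwms, truth=truth,
        promoter_hits=hits, expression=expression,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, config.chrom_name, outdir / "genome.fa")
        write_gene_annotation(genes, outdir / "genes.tsv")
        write_bed(target, outdir / f"{config.target_label}.bed")
        for ref in references:
            write_bed(ref, outdir / f"{ref.label}.bed")
        expression.to_tsv(outdir / "expression.tsv")
        mo.write_jaspar(pwms, outdir / "pwms.jaspar")
        truth.to_json(outdir / "truth.json")
        config.to_json(outdir / "config.json")
    return result


def write_fasta(genome: np.ndarray, chrom_name: str, path, width: int = 80) -> None:
    seq = decode(genome)
    with open(path, "w") as fh:
        fh.write(f">{chrom_name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Matrix-level generator for regression-scale studies


@dataclass
class PromoterHitStudy:
    """One draw of the matrix-level promoter-hit model."""

    hits: list[PromoterHit]
    genes: list[str]
    tfs: list[str]
    scheme: str
    X: np.ndarray  # design matrix under `scheme`
    beta0: float
    beta: np.ndarray
    noise_sd: float
    y: np.ndarray  # log2-scale expression target


def simulate_promoter_hits(
    n_genes: int = 59,
    n_tfs: int = 11,
    scheme: str = "pval_dist",
    bound_prob: float = 0.3,
    beta0: float = 2.0,
    beta: np.ndarray | None = None,
    noise_sd: float | None = None,
    target_r2: float = 0.7,
    seed: int = 0,
) -> PromoterHitStudy:
    """Draw promoter hits directly at the matrix level and generate
    expression under the requested scoring scheme.

    Every (gene, TF) pair gets a hit: with probability ``bound_prob`` the
    TF is "bound" (p = 10^-U(2, 8)), otherwise unbound (p ~ U(0.05, 1)).
    RPKM ~ lognormal(1, 0.7); the unsigned TSS distance is |Normal(0, 1 kb)|
    truncated below 3 kb, shared by all TFs of a gene (one promoter region
    per gene).  Expression is beta0 + X beta + Normal(0, noise_sd), with
    noise_sd calibrated to ``target_r2`` when not given.
    """
    if scheme not in PROMOTER_SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    tfs = [f"TF{j + 1:02d}" for j in range(n_tfs)]
    rpkm = rng.lognormal(1.0, 0.7, size=n_genes)
    dist = np.minimum(np.abs(rng.normal(0.0, 1000.0, size=n_genes)), 2999.0)
    hits: list[PromoterHit] = []
    for i, g in enumerate(genes):
        for j, tf in enumerate(tfs):
            if rng.random() < bound_prob:
                p = 10.0 ** (-rng.uniform(2.0, 8.0))
            else:
                p = rng.uniform(0.05, 1.0)
            hits.append(PromoterHit(tf_name=tf, gene_id=g, p_value=float(p),
                                    rpkm_dhs=float(rpkm[i]),
                                    distance_bp=float(dist[i])))
    X = build_design_matrix(hits, genes, tfs, scheme).scores
    if beta is None:
        # same default as the sequence-level generator: ~60% of TFs are
        # activators with effect U(0.5, 1.5), the rest inert
        active = rng.random(n_tfs) < 0.6
        beta = np.where(active, rng.uniform(0.5, 1.5, size=n_tfs), 0.0)
    beta = np.asarray(beta, dtype=float)
    signal = beta0 + X @ beta
    sd = noise_sd if noise_sd is not None else noise_sd_for_r2(signal, target_r2)
    y = signal + rng.normal(0.0, sd, size=n_genes)
    return PromoterHitStudy(hits=hits, genes=genes, tfs=tfs, scheme=scheme, X=X,
                            beta0=beta0, beta=beta, noise_sd=float(sd), y=y)
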