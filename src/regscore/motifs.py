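"""PWM motif scanning and enrichment against a lognormal chunk background.

The affinity of a sequence for a PWM is the mean, over all windows on both
strands, of the likelihood ratio prod_j p_pwm(b_j) / p_bg(b_j).  The null
model is fitted by tiling background regions into fixed-length chunks
(200 bp by default), scoring each chunk, and taking log affinity to be
Normal(mu, sigma) — i.e. affinity itself is lognormal.  Enrichment of a
foreground of n regions is the upper tail of its mean log affinity under
Normal(mu, sigma / sqrt(n)); per-region p-values use Normal(mu, sigma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

log = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE["N"] = 4
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N

DEFAULT_PSEUDOCOUNT = 0.001
DEFAULT_CHUNK_LEN = 200
MIN_CHUNKS = 100


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as integer codes (N and anything else -> 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in zip("ACGT", range(4)):
        out[arr == ord(base)] = code
    return out


@dataclass
class PWM:
    """Position weight matrix: 4 x L base probabilities plus background."""

    tf_name: str
    matrix: np.ndarray  # shape (4, L), column-stochastic
    background_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM matrix must be 4 x L with L >= 4")
        # pseudocount then renormalise; columns must be stochastic
        self.matrix = self.matrix + self.pseudocount
        self.matrix = self.matrix / self.matrix.sum(axis=0, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def _log_ratio_rows(self) -> np.ndarray:
        """5 x L log likelihood ratios; the N row is 0 (neutral)."""
        rows = np.zeros((5, self.length))
        rows[:4] = np.log(self.matrix) - np.log(self.background_freqs[:, None])
        return rows


def pwm_affinity(sequence: str | np.ndarray, pwm: PWM) -> float:
    """Mean likelihood-ratio affinity of a sequence over both strands.

    Scans every window of length L on the forward and reverse-complement
    strands and averages the per-window likelihood ratios; strictly
    positive, and exactly 1 when the PWM equals its background.
    """
    codes = encode(sequence) if isinstance(sequence, str) else sequence
    L = pwm.length
    n = len(codes) - L + 1
    if n < 1:
        raise ValueError(
            f"sequence length {len(codes)} shorter than motif length {L}"
        )
    rows = pwm._log_ratio_rows()
    # reverse-complement scan == forward scan with the reversed complemented matrix
    rows_rc = rows[_COMPLEMENT][:, ::-1]
    fwd = np.zeros(n)
    rev = np.zeros(n)
    for j in range(L):
        window = codes[j : j + n]
        fwd += rows[:, j][window]
        rev += rows_rc[:, j][window]
    return float(np.mean(np.exp(np.concatenate([fwd, rev]))))


@dataclass
class LognormalBackground:
    pwm_ref: str
    mu: float
    sigma: float
    n_chunks: int
    chunk_len: int = DEFAULT_CHUNK_LEN

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_chunks < MIN_CHUNKS:
            raise ValueError(f"n_chunks must be >= {MIN_CHUNKS}, got {self.n_chunks}")


@dataclass
class MotifEnrichmentResult:
    tf_name: str
    region_id: str  # per-region id, or a group label
    affinity: float  # mean log affinity for group results
    p_value: float
    n_regions: int = 1


def tile_chunks(regions: Iterable[str], chunk_len: int = DEFAULT_CHUNK_LEN) -> list[str]:
    """Tile region sequences into non-overlapping chunks, dropping trailing
    partial chunks."""
    chunks: list[str] = []
    for seq in regions:
        for i in range(0, len(seq) - chunk_len + 1, chunk_len):
            chunks.append(seq[i : i + chunk_len])
    return chunks


def fit_lognormal(log_affinities: np.ndarray) -> tuple[float, float]:
    """(mu, sigma) estimates: mean and sd (ddof=1) of log affinities."""
    logs = np.asarray(log_affinities, dtype=float)
    sigma = float(logs.std(ddof=1))
    # round-off on identical values yields sigma ~ 1e-16, not exactly 0
    if sigma <= 1e-12 * max(1.0, float(np.abs(logs).max())):
        raise ValueError(
            "degenerate background: all chunk affinities identical "
            "(sigma = 0); supply variable background sequence"
        )
    return float(logs.mean()), sigma


def fit_background(
    regions: Iterable[str], pwm: PWM, chunk_len: int = DEFAULT_CHUNK_LEN
) -> LognormalBackground:
    """Fit the lognormal affinity null from tiled background chunks.

    (mu, sigma) are the mean and sd of per-chunk log affinities.
    """
    chunks = tile_chunks(regions, chunk_len)
    if len(chunks) < MIN_CHUNKS:
        raise ValueError(
            f"background too small: {len(chunks)} chunks of {chunk_len} bp "
            f"(need >= {MIN_CHUNKS})"
        )
    mu, sigma = fit_lognormal([np.log(pwm_affinity(c, pwm)) for c in chunks])
    return LognormalBackground(
        pwm_ref=pwm.tf_name,
        mu=mu,
        sigma=sigma,
        n_chunks=len(chunks),
        chunk_len=chunk_len,
    )


_P_FLOOR = np.finfo(float).tiny


def _tail_p(z: float) -> float:
    return float(min(max(stats.norm.sf(z), _P_FLOOR), 1.0))


def enrich(
    foreground: Sequence[str],
    pwm: PWM,
    bg: LognormalBackground,
    region_ids: Sequence[str] | None = None,
    group_label: str = "group",
) -> tuple[MotifEnrichmentResult, list[MotifEnrichmentResult]]:
    """Motif enrichment of a foreground region set against the null.

    Returns the group-level result (upper-tail p of the mean log affinity
    under Normal(mu, sigma / sqrt(n))) and per-region results (under
    Normal(mu, sigma)).
    """
    if len(foreground) == 0:
        raise ValueError("empty foreground")
    if region_ids is None:
        region_ids = [f"region_{i}" for i in range(len(foreground))]
    logs = np.array([np.log(pwm_affinity(seq, pwm)) for seq in foreground])
    n = len(logs)
    group = MotifEnrichmentResult(
        tf_name=pwm.tf_name,
        region_id=group_label,
        affinity=float(logs.mean()),
        p_value=_tail_p((logs.mean() - bg.mu) / (bg.sigma / np.sqrt(n))),
        n_regions=n,
    )
    per_region = [
        MotifEnrichmentResult(
            tf_name=pwm.tf_name,
            region_id=str(rid),
            affinity=float(la),
            p_value=_tail_p((la - bg.mu) / bg.sigma),
        )
        for rid, la in zip(region_ids, logs)
    ]
    return group, per_region


def candidate_tfs(
    results: Sequence[MotifEnrichmentResult],
    expr: pd.DataFrame,
    p_max: float,
    fpkm_min: float = 1.0,
) -> pd.DataFrame:
    """TFs passing the enrichment p-value and expression (mean FPKM) clauses,
    sorted ascending by p-value.

    ``expr`` is the target cell type's gene x replicate FPKM frame; TFs
    absent from it are dropped with a warning.
    """
    mean_fpkm = expr.values.mean(axis=1)
    fpkm = dict(zip((str(g) for g in expr.index), mean_fpkm))
    rows = []
    for r in results:
        if r.tf_name not in fpkm:
            log.warning("candidate_tfs: %s absent from expression table, dropped",
                        r.tf_name)
            continue
        if r.p_value < p_max and fpkm[r.tf_name] > fpkm_min:
            rows.append(
                {
                    "tf": r.tf_name,
                    "n_regions": r.n_regions,
                    "mean_log_affinity": r.affinity,
                    "p_value": r.p_value,
                    "fpkm": fpkm[r.tf_name],
                }
            )
    df = pd.DataFrame(rows, columns=["tf", "n_regions", "mean_log_affinity",
                                     "p_value", "fpkm"])
    return df.sort_values(["p_value", "tf"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# JASPAR I/O (via Bio.motifs)


def read_jaspar(path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Read a JASPAR-format PWM collection (>name header + 4 count rows)."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in records:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        pwms.append(PWM(tf_name=m.name, matrix=counts, pseudocount=pseudocount))
    return pwms


def write_jaspar(pwms: Sequence[PWM], path, scale: float = 100.0) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name}\t{pwm.tf_name}\n")
            for i, base in enumerate(_BASES):
                vals = " ".join(f"{v * scale:.2f}" for v in pwm.matrix[i])
                fh.write(f"{base}  [ {vals} ]\n")
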