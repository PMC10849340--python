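"""Pooled barcode-sequencing screen analysis.

A pooled plasmid library (one unique DNA barcode per gene) is grown under
contrasting conditions; amplicon reads carry an in-line sample index and the
gene barcode at fixed offsets.  This module demultiplexes reads by exact
matching, tests per-gene count enrichment between two conditions with a
conditional binomial exact test, converts p-values into a signed rank
metric, controls FDR with Benjamini-Hochberg, and selects hits.

The enrichment test conditions on the two-condition total ``n = a + b``:
under the null of equal relative abundance, ``a ~ Binomial(n, s_a/(s_a+s_b))``
where ``s_a, s_b`` are the pooled library sizes.  Two-sided p-values sum the
probabilities of all outcomes no more likely than the observed one
(minimum-likelihood rule).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "ReadLayout",
    "BarcodeMaps",
    "CountMatrix",
    "DiscardStats",
    "ScreenConfig",
    "demultiplex_counts",
    "exact_count_test",
    "rank_metric",
    "bh_adjust",
    "run_contrast",
    "select_hits",
]

_DNA = re.compile(r"^[ACGT]+$")

# floor applied to p-values before -log10 in the rank metric
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ReadLayout:
    """Positions of the sample index and gene barcode within a read."""

    index_offset: int = 0
    index_len: int = 6
    barcode_offset: int = 10
    barcode_len: int = 20
    read_len: int = 40

    def __post_init__(self) -> None:
        if self.index_len <= 0 or self.barcode_len <= 0:
            raise ValidationError("index/barcode lengths must be positive")
        if self.index_offset < 0 or self.barcode_offset < 0:
            raise ValidationError("offsets must be >= 0")
        if self.min_read_len > self.read_len:
            raise ValidationError("layout fields exceed read length")

    @property
    def min_read_len(self) -> int:
        return max(
            self.index_offset + self.index_len,
            self.barcode_offset + self.barcode_len,
        )


def _check_map(name: str, mapping: Mapping[str, str]) -> None:
    if not mapping:
        raise ValidationError(f"{name} map is empty")
    lengths = {len(s) for s in mapping.values()}
    if len(lengths) != 1:
        raise ValidationError(f"{name} sequences must have uniform length")
    for s in mapping.values():
        if not _DNA.match(s):
            raise ValidationError(f"{name} sequence {s!r} is not over ACGT")
    if len(set(mapping.values())) != len(mapping):
        raise ValidationError(f"duplicate sequences in {name} map")


@dataclass(frozen=True)
class BarcodeMaps:
    """Gene-barcode and sample-index lookup tables plus the read layout."""

    gene_map: Mapping[str, str]
    index_map: Mapping[str, str]
    layout: ReadLayout = field(default_factory=ReadLayout)

    def __post_init__(self) -> None:
        _check_map("gene barcode", self.gene_map)
        _check_map("sample index", self.index_map)
        bc_len = len(next(iter(self.gene_map.values())))
        ix_len = len(next(iter(self.index_map.values())))
        if bc_len != self.layout.barcode_len:
            raise ValidationError(
                f"barcode length {bc_len} != layout barcode_len {self.layout.barcode_len}"
            )
        if ix_len != self.layout.index_len:
            raise ValidationError(
                f"index length {ix_len} != layout index_len {self.layout.index_len}"
            )


@dataclass
class CountMatrix:
    """Gene-by-sample barcode counts plus per-sample annotations.

    ``counts`` is indexed by gene_id with one column per sample_id;
    ``samples`` is indexed by sample_id with ``condition`` and ``replicate``
    columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be >= 0")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples lack annotations: {sorted(missing)}")
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample table missing column {col!r}")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        return [s for s in self.counts.columns if s in set(sel)]


@dataclass
class DiscardStats:
    """Read accounting from demultiplexing; counted + discarded == total."""

    total: int = 0
    counted: int = 0
    bad_index: int = 0
    bad_barcode: int = 0
    bad_both: int = 0
    too_short: int = 0

    @property
    def discarded(self) -> int:
        return self.bad_index + self.bad_barcode + self.bad_both + self.too_short

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "counted": self.counted,
            "discarded": self.discarded,
            "bad_index": self.bad_index,
            "bad_barcode": self.bad_barcode,
            "bad_both": self.bad_both,
            "too_short": self.too_short,
        }


def _iter_reads(reads) -> Iterator[str]:
    """Yield read sequences from a FASTQ path/handle or an iterable of
    sequences / (id, seq) pairs."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    if isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        if hasattr(reads, "read"):
            for _title, seq, _qual in FastqGeneralIterator(reads):
                yield seq
        else:
            with open(reads) as fh:
                for _title, seq, _qual in FastqGeneralIterator(fh):
                    yield seq
    else:
        for item in reads:
            if isinstance(item, str):
                yield item
            else:
                yield item[1]


def demultiplex_counts(reads, maps: BarcodeMaps) -> tuple[pd.DataFrame, DiscardStats]:
    """Exact-match demultiplexing of barcode reads into a count table.

    A read increments cell ``(gene, sample)`` iff its index field exactly
    equals a mapped sample index AND its barcode field exactly equals a
    mapped gene barcode; anything else is discarded with a reason (bad
    index / bad barcode / both / too short).

    Parameters
    ----------
    reads
        FASTQ file path, open handle, or iterable of sequences or
        ``(id, sequence)`` pairs.

    Returns
    -------
    (counts, stats)
        ``counts`` includes every mapped gene and sample (zeros where no
        read matched).
    """
    lay = maps.layout
    ix_rev = {seq: sid for sid, seq in maps.index_map.items()}
    bc_rev = {seq: gid for gid, seq in maps.gene_map.items()}
    genes = list(maps.gene_map)
    samples = list(maps.index_map)
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(genes), len(samples)), dtype=np.int64)
    stats_ = DiscardStats()

    i0, i1 = lay.index_offset, lay.index_offset + lay.index_len
    b0, b1 = lay.barcode_offset, lay.barcode_offset + lay.barcode_len
    for seq in _iter_reads(reads):
        stats_.total += 1
        if len(seq) < lay.min_read_len:
            stats_.too_short += 1
            continue
        sid = ix_rev.get(seq[i0:i1])
        gid = bc_rev.get(seq[b0:b1])
        if sid is not None and gid is not None:
            mat[gi[gid], si[sid]] += 1
            stats_.counted += 1
        elif sid is None and gid is None:
            stats_.bad_both += 1
        elif sid is None:
            stats_.bad_index += 1
        else:
            stats_.bad_barcode += 1
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    return counts, stats_


def exact_count_test(
    count_a: int, count_b: int, size_a: float, size_b: float
) -> tuple[float, float]:
    """Conditional binomial exact test of differential abundance.

    Given ``n = count_a + count_b``, under the null ``count_a ~
    Binomial(n, size_a / (size_a + size_b))``.  The two-sided p-value sums
    point probabilities <= that of the observed outcome (minimum-likelihood
    rule), capped at 1.  ``log2fc`` is the log2 ratio of pseudocounted
    relative abundances, ``log2(((a + 0.5)/s_a) / ((b + 0.5)/s_b))``.

    ``n = 0`` returns ``(1.0, 0.0)`` by convention.
    """
    if count_a < 0 or count_b < 0:
        raise ValidationError("counts must be >= 0")
    if size_a <= 0 or size_b <= 0:
        raise ValidationError("library sizes must be > 0")
    log2fc = math.log2((count_a + 0.5) / size_a) - math.log2((count_b + 0.5) / size_b)
    n = count_a + count_b
    if n == 0:
        return 1.0, 0.0
    p0 = size_a / (size_a + size_b)
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p0)
    obs = pmf[count_a]
    # relative tolerance guards against ties broken by float rounding
    mask = pmf <= obs * (1.0 + 1e-7)
    if mask.all():  # observed outcome is modal: whole support included
        return 1.0, log2fc
    p = float(pmf[mask].sum())
    # extreme outcomes can underflow the pmf sum to exactly 0; keep p in
    # (0, 1] by flooring at the same floor the rank metric uses
    return min(max(p, P_FLOOR), 1.0), log2fc


def exact_count_test_nb(
    count_a: int, count_b: int, size_a: float, size_b: float, dispersion: float = 0.0
) -> tuple[float, float]:
    """Fixed-dispersion negative-binomial variant of the exact test.

    Conditions on ``n = a + b`` with both condition totals NB-distributed at
    the given dispersion (gamma-Poisson, ``var = mu + dispersion*mu^2``);
    ``dispersion = 0`` reduces to the binomial test.
    """
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    if dispersion == 0:
        return exact_count_test(count_a, count_b, size_a, size_b)
    if count_a < 0 or count_b < 0:
        raise ValidationError("counts must be >= 0")
    if size_a <= 0 or size_b <= 0:
        raise ValidationError("library sizes must be > 0")
    log2fc = math.log2((count_a + 0.5) / size_a) - math.log2((count_b + 0.5) / size_b)
    n = count_a + count_b
    if n == 0:
        return 1.0, 0.0
    # joint null: A ~ NB(mu_a, disp), B ~ NB(mu_b, disp) with mu proportional
    # to library size and mu_a + mu_b = n; condition on A + B = n.
    mu_a = n * size_a / (size_a + size_b)
    mu_b = n - mu_a
    r_a = 1.0 / dispersion
    r_b = 1.0 / dispersion
    k = np.arange(n + 1)
    la = stats.nbinom.logpmf(k, r_a, r_a / (r_a + mu_a))
    lb = stats.nbinom.logpmf(n - k, r_b, r_b / (r_b + mu_b))
    joint = la + lb
    joint -= joint.max()
    pmf = np.exp(joint)
    pmf /= pmf.sum()
    obs = pmf[count_a]
    mask = pmf <= obs * (1.0 + 1e-7)
    if mask.all():
        return 1.0, log2fc
    p = float(pmf[mask].sum())
    return min(max(p, P_FLOOR), 1.0), log2fc


def rank_metric(p_raw: float, log2fc: float) -> float:
    """Signed significance score: sign(enrichment) * -log10(p).

    +1 if the gene is enriched (log2fc > 0), -1 if depleted; zero when
    ``p == 1`` or ``log2fc == 0``.  p-values below 1e-300 are floored
    before the logarithm.
    """
    if not 0 <= p_raw <= 1:
        raise ValidationError(f"p must be in [0, 1], got {p_raw}")
    if p_raw == 1.0 or log2fc == 0.0:
        return 0.0
    sign = 1.0 if log2fc > 0 else -1.0
    return sign * -math.log10(max(p_raw, P_FLOOR))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass(frozen=True)
class ScreenConfig:
    """Contrast-analysis settings."""

    fdr: float = 0.05
    dispersion: float = 0.0  # 0 -> binomial exact test


def _rescale_to_median(counts: pd.DataFrame) -> pd.DataFrame:
    sizes = counts.sum(axis=0).astype(float)
    if (sizes <= 0).any():
        raise ValidationError("every sample must have positive library size")
    target = float(np.median(sizes))
    scaled = counts * (target / sizes)
    return scaled.round().astype(np.int64)


def run_contrast(
    matrix: CountMatrix,
    contrast: tuple[str, str],
    cfg: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Per-gene enrichment between two conditions.

    Replicate samples are rescaled to the common median library size,
    rounded, and pooled per condition; the exact test is applied per gene
    with the pooled totals as sizes; the rank metric and BH-adjusted
    p-values are added.  Genes with zero pooled counts in both conditions
    get ``p = 1`` and a ``low_evidence`` flag.

    Returns a DataFrame indexed by gene_id with columns ``count_a, count_b,
    log2fc, p_raw, p_adj, rank_metric, significant, low_evidence``.
    """
    cfg = cfg or ScreenConfig()
    cond_a, cond_b = contrast
    samples_a = matrix.condition_samples(cond_a)
    samples_b = matrix.condition_samples(cond_b)
    if not samples_a or not samples_b:
        raise ValidationError(f"both conditions of {contrast} need >= 1 sample")
    scaled = _rescale_to_median(matrix.counts[samples_a + samples_b])
    pooled_a = scaled[samples_a].sum(axis=1)
    pooled_b = scaled[samples_b].sum(axis=1)
    size_a = float(pooled_a.sum())
    size_b = float(pooled_b.sum())

    rows = []
    for gene in matrix.counts.index:
        a, b = int(pooled_a[gene]), int(pooled_b[gene])
        if cfg.dispersion > 0:
            p, l2 = exact_count_test_nb(a, b, size_a, size_b, cfg.dispersion)
        else:
            p, l2 = exact_count_test(a, b, size_a, size_b)
        rows.append((gene, a, b, l2, p, a + b == 0))
    res = pd.DataFrame(
        rows, columns=["gene_id", "count_a", "count_b", "log2fc", "p_raw", "low_evidence"]
    ).set_index("gene_id")
    res["p_adj"] = bh_adjust(res["p_raw"].to_numpy())
    res["rank_metric"] = [
        rank_metric(p, l2) for p, l2 in zip(res["p_raw"], res["log2fc"])
    ]
    res["significant"] = res["p_adj"] < cfg.fdr
    return res[
        ["count_a", "count_b", "log2fc", "p_raw", "p_adj", "rank_metric",
         "significant", "low_evidence"]
    ]


def select_hits(
    results: pd.DataFrame,
    mode: str,
    k: int | None = None,
    fdr: float = 0.05,
) -> list[str]:
    """Deterministic hit selection from a contrast result table.

    Rows are ordered by rank_metric descending, ties broken by gene_id
    (lexicographic).  Modes: ``top_k_adaptive`` (k highest rank metrics),
    ``bottom_k`` (k lowest), ``fdr`` (all genes with ``p_adj < fdr``).
    """
    if results.empty:
        raise ValidationError("results table is empty")
    # stable sort: order by gene_id first, then by rank_metric descending,
    # so rank ties resolve lexicographically by gene_id
    ordered = results.sort_index(kind="mergesort").sort_values(
        by="rank_metric", ascending=False, kind="mergesort"
    )
    if mode == "fdr":
        return list(ordered.index[ordered["p_adj"] < fdr])
    if k is None:
        raise ValidationError(f"mode {mode!r} requires k")
    if k > len(ordered):
        warnings.warn(
            f"requested k={k} exceeds table size {len(ordered)}; truncating",
            stacklevel=2,
        )
        k = len(ordered)
    if mode == "top_k_adaptive":
        return list(ordered.index[:k])
    if mode == "bottom_k":
        return list(ordered.index[-k:][::-1])
    raise ValidationError(f"unknown mode {mode!r}")
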