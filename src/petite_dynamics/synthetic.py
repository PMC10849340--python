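"""Synthetic-data generators for every pipeline input.

These emulate the study designs the analysis modules expect: event-driven
stochastic population trajectories (the stochastic counterpart of the
deterministic two-state model), time-resolved petite-count tables with
binomial plating noise, lag/exponential/saturating OD600 curves, bimodal
colony-area tables with label noise, barcode amplicon reads with
substitution errors and a per-read truth table, and multi-condition barcode
count matrices with spiked log2 fold-changes and optional negative-binomial
overdispersion.

Every generator is a pure function of its arguments and a seed: a fixed
seed reproduces the output exactly.  Cultures are assumed to stay in
exponential phase (constant rates, no density dependence), matching
experiments that hold density below 0.5 OD by dilution; the documented
OD-to-cells conversion is 1 OD = 1e7 cells.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .screen import CountMatrix, ReadLayout
from .two_state import PopulationTrajectory, TwoStateParams, mutant_fraction_at

__all__ = [
    "OD_TO_CELLS",
    "simulate_population_stochastic",
    "generate_petite_time_series",
    "generate_growth_curve",
    "generate_colony_areas",
    "random_dna",
    "make_barcode_maps",
    "generate_barcode_reads",
    "generate_screen_counts",
]

# extinction-coefficient convention used for cell-count estimation
OD_TO_CELLS = 1e7

_BASES = np.array(list("ACGT"))


def simulate_population_stochastic(
    params: TwoStateParams,
    t_end: float,
    seed: int,
    max_population: int = 1_000_000,
) -> PopulationTrajectory:
    """Exact event-driven (Gillespie) simulation of the two-state process.

    Events and their propensities: rho+ division (``g_wt`` per rho+ cell),
    rho+ -> rho0 conversion (``r`` per rho+ cell), rho0 division (``g_mut``
    per rho0 cell).  Growth constants must be >= 0 (branching process; no
    death events).  Initial abundances must be integers.

    Returns the full event-resolved trajectory (state after each event,
    plus the initial state and the final state at ``t_end``).  If the total
    population reaches ``max_population`` the simulation truncates there
    with a warning.
    """
    if t_end < 0:
        raise ValidationError("t_end must be >= 0")
    if params.g_wt < 0 or params.g_mut < 0:
        raise ValidationError("stochastic simulation requires g_wt, g_mut >= 0")
    n_wt, n_mut = params.p_wt0, params.p_mut0
    if n_wt != int(n_wt) or n_mut != int(n_mut):
        raise ValidationError("initial abundances must be integers")
    n_wt, n_mut = int(n_wt), int(n_mut)

    rng = np.random.default_rng(seed)
    times = [0.0]
    wt = [n_wt]
    mut = [n_mut]
    t = 0.0
    while True:
        rate_div_wt = params.g_wt * n_wt
        rate_conv = params.r * n_wt
        rate_div_mut = params.g_mut * n_mut
        total_rate = rate_div_wt + rate_conv + rate_div_mut
        if total_rate <= 0:
            break
        t += rng.exponential(1.0 / total_rate)
        if t >= t_end:
            break
        u = rng.random() * total_rate
        if u < rate_div_wt:
            n_wt += 1
        elif u < rate_div_wt + rate_conv:
            n_wt -= 1
            n_mut += 1
        else:
            n_mut += 1
        times.append(t)
        wt.append(n_wt)
        mut.append(n_mut)
        if n_wt + n_mut >= max_population:
            warnings.warn(
                f"population reached cap {max_population} at t={t:.3f} h; "
                "trajectory truncated",
                stacklevel=2,
            )
            return PopulationTrajectory(
                times=np.array(times), p_wt=np.array(wt, float),
                p_mut=np.array(mut, float),
            )
    times.append(t_end)
    wt.append(n_wt)
    mut.append(n_mut)
    return PopulationTrajectory(
        times=np.array(times), p_wt=np.array(wt, float), p_mut=np.array(mut, float)
    )


def generate_petite_time_series(
    params: TwoStateParams,
    sampling_times: Sequence[float],
    colonies_per_plate: float,
    n_replicates: int,
    baseline_fraction: float = 0.0,
    seed: int = 0,
    genotype: str = "synthetic",
) -> pd.DataFrame:
    """Colony-count table from plating a culture at successive timepoints.

    The underlying mutant fraction follows the deterministic model started
    from ``baseline_fraction``; per replicate and timepoint the number of
    colonies is Poisson around ``colonies_per_plate`` (resampled if zero)
    and the petite count is Binomial(n_total, f(t)).

    Returns a DataFrame with columns ``replicate, genotype, time_h,
    n_total, n_petite``.
    """
    if not 0 <= baseline_fraction < 1:
        raise ValidationError("baseline_fraction must be in [0, 1)")
    if n_replicates <= 0 or colonies_per_plate <= 0:
        raise ValidationError("replicates and colony density must be positive")
    p = params.with_initial_fraction(baseline_fraction)
    t = np.asarray(sampling_times, dtype=float)
    f = np.atleast_1d(mutant_fraction_at(p, t))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for tj, fj in zip(t, f):
            n_total = 0
            while n_total == 0:
                n_total = int(rng.poisson(colonies_per_plate))
            n_petite = int(rng.binomial(n_total, fj))
            rows.append((f"rep{rep:02d}", genotype, float(tj), n_total, n_petite))
    return pd.DataFrame(
        rows, columns=["replicate", "genotype", "time_h", "n_total", "n_petite"]
    )


def generate_growth_curve(
    rate: float,
    lag_h: float = 0.5,
    initial_od: float = 0.015,
    capacity_od: float = 1.2,
    noise_sd: float = 0.002,
    interval_min: float = 20.0,
    duration_h: float = 24.0,
    seed: int = 0,
    curve_id: str = "sim",
):
    """Plate-reader OD600 time series: lag, exponential phase, saturation,
    plus additive Gaussian noise.

    The deterministic backbone is exponential growth from ``initial_od``
    after ``lag_h``, blended into the carrying capacity by a sharp
    soft-minimum (p-norm, p=8), so the sub-saturation phase is genuinely
    exponential at ``rate`` while the curve levels off at ``capacity_od``.
    With ``noise_sd = 0`` and ``capacity_od`` far above the observed range
    the samples equal ``initial_od * exp(rate * (t - lag))`` exactly.
    Times are in minutes (instrument convention), the rate per hour.
    """
    from .growth import GrowthCurve

    if rate < 0:
        raise ValidationError("rate must be >= 0")
    if capacity_od <= initial_od:
        raise ValidationError("capacity_od must exceed initial_od")
    times_min = np.arange(0.0, duration_h * 60.0 + 0.5 * interval_min, interval_min)
    t_eff = np.maximum(times_min / 60.0 - lag_h, 0.0)
    expo = initial_od * np.exp(rate * t_eff)
    p = 8.0
    od = expo / (1.0 + (expo / capacity_od) ** p) ** (1.0 / p)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return GrowthCurve(curve_id=curve_id, times_min=times_min, od600=od)


def generate_colony_areas(
    n: int,
    petite_fraction: float,
    mu_small: float = -0.7,
    sd_small: float = 0.30,
    mu_large: float = 1.4,
    sd_large: float = 0.30,
    label_noise: float = 0.0,
    seed: int = 0,
    plate_id: str = "plate1",
) -> pd.DataFrame:
    """Bimodal colony-area table with respiration labels.

    Areas (mm^2) are log-normal: a small (petite, non-respiring) component
    with log-mean ``mu_small`` (default ~0.5 mm^2) and a large (respiring)
    component with log-mean ``mu_large`` (default ~4 mm^2).  A
    ``label_noise`` fraction of respiration labels is flipped, emulating
    mislabeled patches.

    Returns a DataFrame with columns ``plate_id, colony_id, area_mm2,
    respiring``.
    """
    if not 0 <= petite_fraction <= 1:
        raise ValidationError("petite_fraction must be in [0, 1]")
    if not 0 <= label_noise < 0.5:
        raise ValidationError("label_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    is_petite = rng.random(n) < petite_fraction
    areas = np.where(
        is_petite,
        rng.lognormal(mu_small, sd_small, size=n),
        rng.lognormal(mu_large, sd_large, size=n),
    )
    respiring = ~is_petite
    if label_noise > 0:
        flip = rng.random(n) < label_noise
        respiring = respiring ^ flip
    return pd.DataFrame(
        {
            "plate_id": plate_id,
            "colony_id": [f"c{i:04d}" for i in range(1, n + 1)],
            "area_mm2": areas,
            "respiring": respiring,
        }
    )


def random_dna(n: int, length: int, seed: int = 0) -> list[str]:
    """``n`` distinct random DNA sequences of the given length."""
    rng = np.random.default_rng(seed)
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        s = "".join(rng.choice(_BASES, size=length))
        if s not in seqs:
            seqs.add(s)
            out.append(s)
    return out


def make_barcode_maps(
    gene_ids: Sequence[str],
    sample_ids: Sequence[str],
    layout: ReadLayout | None = None,
    seed: int = 0,
):
    """Random gene-barcode and sample-index maps consistent with a layout."""
    from .screen import BarcodeMaps

    layout = layout or ReadLayout()
    barcodes = random_dna(len(gene_ids), layout.barcode_len, seed=seed)
    indexes = random_dna(len(sample_ids), layout.index_len, seed=seed + 1)
    return BarcodeMaps(
        gene_map=dict(zip(gene_ids, barcodes)),
        index_map=dict(zip(sample_ids, indexes)),
        layout=layout,
    )


def generate_barcode_reads(
    true_counts: pd.DataFrame,
    maps,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Amplicon reads for a known count table, with per-base substitution
    errors and a truth table.

    Each read carries its sample's index sequence and its gene's barcode at
    the layout's offsets, padded with deterministic filler bases.  Every
    base is substituted independently with probability ``error_rate``
    (substitutions always change the base).  The truth table records, per
    read, the intended (sample, gene) and the number of injected errors
    inside the index and barcode fields, which predicts exactly which reads
    exact-match demultiplexing will discard.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)``
    pairs and truth has columns ``read_id, sample_id, gene_id,
    index_errors, barcode_errors``.
    """
    if not 0 <= error_rate <= 1:
        raise ValidationError("error_rate must be in [0, 1]")
    lay = maps.layout
    rng = np.random.default_rng(seed)
    filler = np.array(list("A" * lay.read_len))
    i0, i1 = lay.index_offset, lay.index_offset + lay.index_len
    b0, b1 = lay.barcode_offset, lay.barcode_offset + lay.barcode_len

    reads: list[tuple[str, str]] = []
    truth_rows = []
    k = 0
    for sample in true_counts.columns:
        ix = maps.index_map[sample]
        for gene in true_counts.index:
            c = int(true_counts.loc[gene, sample])
            if c < 0:
                raise ValidationError("true counts must be >= 0")
            bc = maps.gene_map[gene]
            for _ in range(c):
                k += 1
                arr = filler.copy()
                arr[i0:i1] = list(ix)
                arr[b0:b1] = list(bc)
                ne_ix = ne_bc = 0
                if error_rate > 0:
                    hits = np.nonzero(rng.random(lay.read_len) < error_rate)[0]
                    for pos in hits:
                        old = arr[pos]
                        choices = _BASES[_BASES != old]
                        arr[pos] = choices[rng.integers(3)]
                        if i0 <= pos < i1:
                            ne_ix += 1
                        elif b0 <= pos < b1:
                            ne_bc += 1
                rid = f"read{k:07d}"
                reads.append((rid, "".join(arr)))
                truth_rows.append((rid, sample, gene, ne_ix, ne_bc))
    # shuffle so reads are not grouped by cell of origin
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample_id", "gene_id", "index_errors", "barcode_errors"],
    ).iloc[order].reset_index(drop=True)
    return reads, truth


def generate_screen_counts(
    n_genes: int = 1000,
    n_reps: int = 3,
    library_size: int = 1_000_000,
    conditions: Sequence[str] = ("control", "etbr"),
    spike_effects: Mapping[str, Mapping[str, float]] | None = None,
    dispersion: float = 0.0,
    seed: int = 0,
) -> CountMatrix:
    """Multi-condition barcode count matrix with spiked log2 fold-changes.

    Per-gene baseline abundances are log-normal; each condition's expected
    proportions multiply the baseline by ``2**effect`` for spiked genes
    (effects are relative to the first condition) and renormalize.  Counts
    are Poisson around ``library_size * proportion``; with ``dispersion >
    0`` the Poisson mean is gamma-mixed per sample, yielding negative-
    binomial marginals with ``var = mu + dispersion * mu^2``.

    Gene ids are ``g0001...``; sample ids ``{condition}_r{replicate}``.
    """
    if n_genes <= 0 or n_reps <= 0 or library_size <= 0:
        raise ValidationError("n_genes, n_reps, library_size must be positive")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    spike_effects = spike_effects or {}
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    gidx = {g: i for i, g in enumerate(genes)}
    for g, eff in spike_effects.items():
        if g not in gidx:
            raise ValidationError(f"spiked gene {g!r} not in matrix")
        if not all(np.isfinite(list(eff.values()))):
            raise ValidationError("spike effects must be finite")
    base = rng.lognormal(0.0, 1.0, size=n_genes)

    cols = {}
    sample_rows = []
    for cond in conditions:
        mult = np.ones(n_genes)
        for g, eff in spike_effects.items():
            mult[gidx[g]] = 2.0 ** eff.get(cond, 0.0)
        props = base * mult
        props = props / props.sum()
        for rep in range(1, n_reps + 1):
            mu = library_size * props
            if dispersion > 0:
                shape = 1.0 / dispersion
                mu = mu * rng.gamma(shape, 1.0 / shape, size=n_genes)
            cols[f"{cond}_r{rep}"] = rng.poisson(mu)
            sample_rows.append((f"{cond}_r{rep}", cond, rep))
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "condition", "replicate"]
    ).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples)
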