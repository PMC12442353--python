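"""Synthetic DNA-SIP experiment generator.

Emulates the statistical structure of a soil-microcosm stable isotope
probing study: a bacterial community with known GC content, 16S rRNA gene
copy number (rrn) and per-substrate atom-fraction ¹³C enrichment is banded
in a CsCl buoyant-density gradient, fractionated and "sequenced"
(multinomial counts per fraction); the same community is sampled over time
in bulk soil with rrn-dependent lag and logistic growth; and headspace
¹³CO₂ is respired according to substrate-specific rate curves with known
peak days.  Every generator is deterministic under an integer seed, and the
ground truth is retained so downstream incorporator calls, growth traits
and peak-day estimates can be scored against it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import pdist
from scipy.stats import norm
from skbio import TreeNode

from .exceptions import DomainError, InvalidDesignError
from .gradient_sip import FractionTable

SUBSTRATES = ("xylose", "cellulose")

#: Default per-substrate lag windows (days) for incorporator growth onset.
#: The soluble substrate is consumed quickly after addition; the insoluble
#: polymer requires depolymerisation first, so its consumers start later.
DEFAULT_LAG_RANGES = {"xylose": (0.0, 4.0), "cellulose": (2.0, 8.0)}


@dataclass(frozen=True)
class DensityModel:
    """Linear GC → buoyant density map with a labeling shift.

    ``intercept`` and ``slope`` follow the classical linear relation between
    genomic GC fraction and CsCl buoyant density (1.660 + 0.098·GC g/mL);
    ``max_shift`` is the density gain of fully ¹³C-labeled DNA.
    """

    intercept: float = 1.660
    slope: float = 0.098
    max_shift: float = 0.036

    def __post_init__(self) -> None:
        if self.max_shift <= 0:
            raise InvalidDesignError("max_shift must be positive")


@dataclass(frozen=True)
class GradientDesign:
    """Fractionation design for one isopycnic centrifugation run."""

    bd_min: float = 1.67
    bd_max: float = 1.78
    n_fractions: int = 24
    band_sigma: float = 0.005
    seq_depth: int = 10_000
    background: float = 0.02
    density_model: DensityModel = field(default_factory=DensityModel)

    def __post_init__(self) -> None:
        if not self.bd_min < self.bd_max:
            raise InvalidDesignError("bd_min must be below bd_max")
        if self.n_fractions < 2:
            raise InvalidDesignError("need at least 2 fractions")
        if self.band_sigma <= 0:
            raise InvalidDesignError("band_sigma must be positive")
        if self.seq_depth <= 0:
            raise InvalidDesignError("seq_depth must be positive")
        if not 0 <= self.background < 1:
            raise InvalidDesignError("background must lie in [0, 1)")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.bd_min, self.bd_max, self.n_fractions + 1)

    @property
    def midpoints(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class CommunityTruth:
    """Ground-truth community used by all generators.

    ``table`` holds per-taxon parameters (gc, rrn, base_abundance, lag_days,
    growth_rate, max_fold); ``enrichment`` is a taxon × substrate matrix of
    atom-fraction-excess ¹³C.  A taxon is an incorporator of a substrate iff
    its enrichment for that substrate is nonzero; enrichment only takes
    effect on days at or after the taxon's lag (labeling requires growth).
    """

    table: pd.DataFrame
    enrichment: pd.DataFrame
    substrates: tuple[str, ...] = SUBSTRATES

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["gc"] >= 0) & (t["gc"] <= 1)).all():
            raise DomainError("gc must lie in [0, 1]")
        if not ((self.enrichment >= 0) & (self.enrichment <= 1)).all().all():
            raise DomainError("enrichment must lie in [0, 1]")
        if (t["lag_days"] < 0).any():
            raise DomainError("lag_days must be nonnegative")
        if (t["rrn"] <= 0).any():
            raise DomainError("rrn must be positive")
        total = t["base_abundance"].sum()
        if not np.isclose(total, 1.0):
            raise DomainError("base abundances must sum to 1")

    @property
    def taxon_ids(self) -> pd.Index:
        return self.table.index

    def is_incorporator(self, substrate: str) -> pd.Series:
        return self.enrichment[substrate] > 0

    def enrichment_at(self, substrate: str, day: float) -> pd.Series:
        """Effective atom-fraction excess on a given day (zero before lag)."""
        active = (self.table["lag_days"] <= day) & self.is_incorporator(substrate)
        return self.enrichment[substrate].where(active, 0.0)


@dataclass(frozen=True)
class MineralizationTruth:
    """Parameters of one substrate's respiration curve.

    ``shape`` selects the rate archetype: ``pulse`` (rapid use of a soluble
    substrate, rate ∝ (t/τ)·exp(1 − t/τ), peak at τ) or ``logistic`` (lagged
    use of an insoluble substrate, rate ∝ sech²((t − τ)/w), peak at τ).
    ``respired_frac`` is the fraction of added substrate C mineralized to
    CO₂ by the end of the incubation (the rest is assimilated or remains).
    """

    substrate: str
    peak_day: float
    total_c: float
    shape: str = "pulse"
    width: float = 1.5
    respired_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.total_c < 0:
            raise DomainError("total_c must be nonnegative")
        if self.peak_day < 0:
            raise DomainError("peak_day must be nonnegative")
        if not 0 <= self.respired_frac <= 1:
            raise DomainError("respired_frac must lie in [0, 1]")
        if self.shape not in {"pulse", "logistic"}:
            raise InvalidDesignError(f"unknown rate shape {self.shape!r}")

    def rate(self, t: np.ndarray) -> np.ndarray:
        """Relative instantaneous mineralization rate at times ``t`` (days)."""
        t = np.asarray(t, dtype=float)
        if self.shape == "pulse":
            tau = max(self.peak_day, 1e-9)
            r = (t / tau) * np.exp(1.0 - t / tau)
        else:
            r = 1.0 / np.cosh((t - self.peak_day) / self.width) ** 2
        return np.where(t >= 0, r, 0.0)


def simulate_community(
    n_taxa: int,
    frac_incorporators_per_substrate: float = 0.1,
    seed: int = 0,
    *,
    substrates: tuple[str, ...] = SUBSTRATES,
    gc_range: tuple[float, float] = (0.35, 0.70),
    enrichment_range: tuple[float, float] = (1.0, 1.0),
    lag_ranges: dict[str, tuple[float, float]] | None = None,
    growth_rate_range: tuple[float, float] = (0.8, 1.6),
    max_fold_range: tuple[float, float] = (4.0, 32.0),
    abundance_sigma: float = 0.8,
    rrn_range: tuple[float, float] = (1.0, 12.0),
    soluble_rrn_bias: bool = True,
) -> CommunityTruth:
    """Draw a ground-truth community.

    Parameters
    ----------
    n_taxa : int
        Number of taxa (ASVs); must be ≥ 2.
    frac_incorporators_per_substrate : float
        Fraction of taxa flagged as incorporators of each substrate (drawn
        independently per substrate, so dual incorporators occur).
    seed : int
        Seed for all random draws; identical calls are byte-identical.
    soluble_rrn_bias : bool
        When True, xylose (soluble-substrate) incorporators draw rrn from
        the upper part of ``rrn_range`` and cellulose-only incorporators
        from the lower part, emulating the ruderal/high-rrn association
        with labile carbon.
    """
    if n_taxa < 2:
        raise InvalidDesignError("n_taxa must be at least 2")
    if not 0 <= frac_incorporators_per_substrate <= 1:
        raise InvalidDesignError("frac_incorporators_per_substrate must lie in [0, 1]")
    lag_ranges = dict(DEFAULT_LAG_RANGES) if lag_ranges is None else lag_ranges

    rng = np.random.default_rng(seed)
    ids = pd.Index([f"ASV{i:04d}" for i in range(n_taxa)], name="taxon_id")

    gc = rng.uniform(*gc_range, size=n_taxa)
    base = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_taxa)
    base = base / base.sum()

    n_inc = int(round(frac_incorporators_per_substrate * n_taxa))
    enr = pd.DataFrame(0.0, index=ids, columns=list(substrates))
    lag = np.zeros(n_taxa)
    for sub in substrates:
        chosen = rng.choice(n_taxa, size=n_inc, replace=False)
        if n_inc:
            enr.iloc[chosen, enr.columns.get_loc(sub)] = rng.uniform(
                *enrichment_range, size=n_inc
            )
            lo, hi = lag_ranges.get(sub, (0.0, 6.0))
            lag[chosen] = np.maximum(lag[chosen], rng.uniform(lo, hi, size=n_inc))

    any_inc = (enr > 0).any(axis=1).to_numpy()
    growth = np.where(any_inc, rng.uniform(*growth_rate_range, size=n_taxa), 0.0)
    max_fold = np.where(any_inc, rng.uniform(*max_fold_range, size=n_taxa), 1.0)

    lo, hi = rrn_range
    rrn = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_taxa))
    if soluble_rrn_bias and "xylose" in substrates:
        xyl = (enr["xylose"] > 0).to_numpy()
        mid = np.sqrt(lo * hi)
        rrn[xyl] = np.exp(rng.uniform(np.log(mid), np.log(hi), size=xyl.sum()))
        cel_only = (~xyl) & any_inc
        rrn[cel_only] = np.exp(
            rng.uniform(np.log(lo), np.log(mid), size=cel_only.sum())
        )

    table = pd.DataFrame(
        {
            "gc": gc,
            "rrn": rrn,
            "base_abundance": base,
            "lag_days": lag,
            "growth_rate": growth,
            "max_fold": max_fold,
        },
        index=ids,
    )
    return CommunityTruth(table=table, enrichment=enr, substrates=tuple(substrates))


def gc_to_density(gc, density_model: DensityModel | None = None):
    """Buoyant density (g/mL) of unlabeled DNA of the given GC fraction."""
    model = density_model or DensityModel()
    gc = np.asarray(gc, dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise DomainError("gc must lie in [0, 1]")
    out = model.intercept + model.slope * gc
    return float(out) if out.ndim == 0 else out


def labeled_density(gc, atom_excess, density_model: DensityModel | None = None):
    """Buoyant density of DNA with the given atom-fraction-excess ¹³C."""
    model = density_model or DensityModel()
    atom_excess = np.asarray(atom_excess, dtype=float)
    if np.any((atom_excess < 0) | (atom_excess > 1)):
        raise DomainError("atom_excess must lie in [0, 1]")
    out = gc_to_density(gc, model) + atom_excess * model.max_shift
    return float(out) if out.ndim == 0 else out


def simulate_gradient(
    truth: CommunityTruth,
    design: GradientDesign,
    isotope: str,
    substrate: str,
    day: float,
    seed: int = 0,
    gradient_id: str | None = None,
) -> FractionTable:
    """Band the community in a density gradient and sequence each fraction.

    Each taxon's reads band around its (possibly labeled) buoyant density
    with Gaussian spread ``band_sigma``, plus a small diffuse component
    (``design.background`` of each taxon's mass spread uniformly over the
    sampled density range) emulating the non-equilibrium DNA smear real
    CsCl gradients exhibit in every fraction.  The expected composition of
    a fraction is the abundance-weighted mass falling inside the fraction's
    density interval, and observed counts are a multinomial sample of
    ``seq_depth`` reads per fraction.  ¹²C runs ignore enrichment.
    """
    if isotope not in {"12C", "13C"}:
        raise InvalidDesignError(f"isotope must be 12C or 13C, got {isotope!r}")
    rng = np.random.default_rng(seed)
    gc = truth.table["gc"].to_numpy()
    if isotope == "13C":
        excess = truth.enrichment_at(substrate, day).to_numpy()
    else:
        excess = np.zeros(len(gc))
    centers = labeled_density(gc, excess, design.density_model)

    edges = design.edges
    z = (edges[None, :] - centers[:, None]) / design.band_sigma
    mass = np.diff(norm.cdf(z), axis=1)  # taxa × fractions
    smear = np.diff(edges) / (design.bd_max - design.bd_min)
    mass = (1.0 - design.background) * mass + design.background * smear[None, :]
    weights = truth.table["base_abundance"].to_numpy()[:, None] * mass
    weights = weights + 1e-300  # guard empty far-tail fractions

    counts = np.empty((len(gc), design.n_fractions), dtype=np.int64)
    for j in range(design.n_fractions):
        p = weights[:, j] / weights[:, j].sum()
        counts[:, j] = rng.multinomial(design.seq_depth, p)

    gid = gradient_id or f"{isotope}_{substrate}_d{day:g}"
    samples = [f"{gid}_F{j:02d}" for j in range(design.n_fractions)]
    frame = pd.DataFrame(counts, index=truth.taxon_ids, columns=samples)
    bd = pd.Series(design.midpoints, index=samples, name="fraction_bd")
    return FractionTable(counts=frame, fraction_bd=bd, gradient_id=gid)


def expected_abundance(truth: CommunityTruth, day: float) -> pd.Series:
    """Closed-form cell abundance of every taxon on a given day.

    Lagged logistic growth: abundance stays at baseline until ``lag_days``,
    then follows the logistic solution toward carrying capacity
    ``base_abundance × max_fold`` at rate ``growth_rate`` per day.
    """
    t = truth.table
    b = t["base_abundance"].to_numpy()
    k = b * t["max_fold"].to_numpy()
    r = t["growth_rate"].to_numpy()
    dt = np.maximum(np.asarray(day, dtype=float) - t["lag_days"].to_numpy(), 0.0)
    with np.errstate(over="ignore"):
        a = k / (1.0 + ((k - b) / b) * np.exp(-r * dt))
    a = np.where((r <= 0) | (dt <= 0), b, a)
    return pd.Series(a, index=truth.taxon_ids)


def simulate_timeseries(
    truth: CommunityTruth,
    days,
    total_depth: int = 20_000,
    seed: int = 0,
    dna_yield0: float = 10.0,
):
    """Bulk community time series after carbon addition at day 0.

    Returns ``(counts, dna_yield)``: a taxa × day count table (multinomial
    samples of 16S copy abundance, i.e. cell abundance × rrn, at
    ``total_depth`` reads per day) and a per-day DNA yield (ng/µL)
    proportional to total community biomass — the proxy contract used when
    weighting normalized abundances.
    """
    days = list(days)
    if len(days) == 0 or any(b <= a for a, b in zip(days, days[1:])):
        raise InvalidDesignError("days must be nonempty and strictly ascending")
    if total_depth <= 0:
        raise InvalidDesignError("total_depth must be positive")
    rng = np.random.default_rng(seed)
    rrn = truth.table["rrn"].to_numpy()
    base_biomass = truth.table["base_abundance"].sum()

    cols, yields = {}, {}
    for day in days:
        cells = expected_abundance(truth, day).to_numpy()
        copies = cells * rrn
        p = copies / copies.sum()
        cols[f"d{day:g}"] = rng.multinomial(total_depth, p)
        yields[f"d{day:g}"] = dna_yield0 * cells.sum() / base_biomass
    counts = pd.DataFrame(cols, index=truth.taxon_ids)
    dna_yield = pd.Series(yields, name="dna_yield")
    return counts, dna_yield


def simulate_mineralization(
    mtruth: MineralizationTruth,
    timepoints,
    tillage: str = "NTH",
    n_replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    c12_ratio: float = 1.0,
) -> pd.DataFrame:
    """Respired C per flush interval at the given timepoints (days).

    The mass assigned to the interval ending at t_k is the instantaneous
    rate at t_k times the interval duration, normalized so the series sums
    to ``respired_frac × total_c``; the headspace is assumed fully flushed
    at each measurement so intervals are independent.  Returns a long table
    with columns timepoint_d, timepoint_h, c13_mg, c12_mg, substrate,
    tillage, replicate.
    """
    t = np.asarray(list(timepoints), dtype=float)
    if t.size == 0:
        raise InvalidDesignError("timepoints must be nonempty")
    if np.any(t < 0):
        raise DomainError("timepoints must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise InvalidDesignError("timepoints must be strictly ascending")
    rng = np.random.default_rng(seed)

    durations = np.diff(np.concatenate([[0.0], t]))
    w = mtruth.rate(t) * durations
    total_mass = mtruth.respired_frac * mtruth.total_c
    base = w / w.sum() * total_mass if w.sum() > 0 else np.zeros_like(w)

    rows = []
    for rep in range(1, n_replicates + 1):
        m = base.copy()
        if noise_sd > 0:
            m = m * rng.lognormal(0.0, noise_sd, size=m.size)
            if m.sum() > mtruth.total_c > 0:
                m *= mtruth.total_c / m.sum()
        rows.append(
            pd.DataFrame(
                {
                    "timepoint_d": t,
                    "timepoint_h": t * 24.0,
                    "c13_mg": m,
                    "c12_mg": m * c12_ratio,
                    "substrate": mtruth.substrate,
                    "tillage": tillage,
                    "replicate": rep,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_tree(taxon_ids, seed: int = 0) -> TreeNode:
    """Random ultrametric tree over the given taxa (UPGMA on random traits)."""
    ids = list(taxon_ids)
    if len(ids) < 2:
        raise InvalidDesignError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    coords = rng.normal(size=(len(ids), 5))
    tree = TreeNode.from_linkage_matrix(average(pdist(coords)), ids)
    tree = tree.root()
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
    return tree


def simulate_brownian_traits(
    tree: TreeNode, n_traits: int = 3, sigma: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Continuous traits evolved on the tree under Brownian motion.

    Tip covariance equals the shared root-to-MRCA path length, computed for
    an ultrametric tree as tip depth minus half the cophenetic distance.
    """
    rng = np.random.default_rng(seed)
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    d = dm.data
    depth = np.max(d) / 2.0
    cov = sigma**2 * (depth - d / 2.0)
    cov = cov + 1e-9 * np.eye(len(ids))
    x = rng.multivariate_normal(np.zeros(len(ids)), cov, size=n_traits).T
    return pd.DataFrame(x, index=pd.Index(ids, name="taxon_id"),
                        columns=[f"trait{i}" for i in range(n_traits)])


def write_truth(truth: CommunityTruth, table_path, enrichment_path) -> None:
    """Write ground-truth tables as TSV."""
    truth.table.to_csv(table_path, sep="\t")
    truth.enrichment.to_csv(enrichment_path, sep="\t")
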