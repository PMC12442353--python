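"""End-to-end orchestration: simulate → identify → traits → mineralization → phylo.

``run_pipeline`` executes the full analysis over either a simulated
experiment (when the config carries a ``simulate`` section) or user-supplied
input files, writing every stage's outputs as TSV plus a machine-readable
run manifest.  All randomness descends from the single configured seed via
per-stage spawned substreams, so reruns with the same config are
byte-identical and stages remain individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .exceptions import InvalidDesignError
from .gradient_sip import (
    DEFAULT_SPARSITY_GRID,
    DEFAULT_WINDOWS,
    FractionTable,
    mw_hr_sip,
)
from .growth_traits import (
    DEFAULT_RAREFY_DEPTH,
    build_trait_table,
    compare_groups,
    rarefy,
)
from .mineralization import cumulative_mineralization, mineralization_rate, peak_day_summary
from .phylo_function import (
    cophenetic_distance,
    distance_correlation,
    functional_distance_matrix,
    scale_traits,
)
from .synthetic_data import (
    SUBSTRATES,
    CommunityTruth,
    GradientDesign,
    MineralizationTruth,
    simulate_community,
    simulate_gradient,
    simulate_mineralization,
    simulate_timeseries,
    simulate_tree,
    write_truth,
)

logger = logging.getLogger(__name__)

DEFAULT_DAYS = {"xylose": [1, 3, 7, 14], "cellulose": [3, 7, 14, 30]}
DEFAULT_PEAKS = {"xylose": 2.0, "cellulose": 6.0}


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "mwsip_out"
    simulate: dict | None = None
    counts: str | None = None
    metadata: str | None = None
    rrn: str | None = None
    tree: str | None = None
    mineralization: str | None = None
    windows: list = field(default_factory=lambda: [list(w) for w in DEFAULT_WINDOWS])
    l2fc_null: float = 0.25
    padj_cut: float = 0.1
    sparsity_grid: list = field(default_factory=lambda: list(DEFAULT_SPARSITY_GRID))
    rarefy_depth: int = DEFAULT_RAREFY_DEPTH
    n_perm: int = 999
    days: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_DAYS.items()})
    tillage_regimes: list = field(default_factory=lambda: ["NTH"])
    run_phylofunc: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise InvalidDesignError("seed must be an integer")
        if not 0 < self.padj_cut < 1:
            raise InvalidDesignError("padj_cut must lie in (0, 1)")
        if self.rarefy_depth < 1:
            raise InvalidDesignError("rarefy_depth must be positive")
        if self.simulate is None:
            required = {"counts": self.counts, "metadata": self.metadata, "rrn": self.rrn}
            if self.run_phylofunc:
                required["tree"] = self.tree
            for name, path in required.items():
                if path is None:
                    raise InvalidDesignError(
                        f"config needs either a 'simulate' section or a {name!r} path"
                    )
                if not Path(path).exists():
                    raise InvalidDesignError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit stage seeds from the run seed."""
    return [
        int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for ss in np.random.SeedSequence(seed).spawn(n)
    ]


def _simulated_inputs(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = dict(cfg.simulate or {})
    n_taxa = int(sim.pop("n_taxa", 100))
    frac = float(sim.pop("frac_incorporators_per_substrate", 0.1))
    design = GradientDesign(**sim.pop("gradient", {}))
    bulk_depth = int(sim.pop("bulk_depth", 20_000))
    total_c = sim.pop("total_c", {"xylose": 1.6, "cellulose": 1.6})
    n_reps = int(sim.pop("mineralization_replicates", 3))
    noise_sd = float(sim.pop("mineralization_noise_sd", 0.05))
    if sim:
        raise InvalidDesignError(f"unknown simulate options: {sorted(sim)}")

    bundle: dict = {"tillages": {}}
    for k, tillage in enumerate(cfg.tillage_regimes):
        s_comm, s_grad, s_bulk, s_min, s_tree = _spawn_seeds(cfg.seed + 7919 * k, 5)
        truth = simulate_community(n_taxa, frac, seed=s_comm)
        tree = simulate_tree(truth.taxon_ids, seed=s_tree)
        write_truth(truth, outdir / f"truth_community_{tillage}.tsv",
                    outdir / f"truth_enrichment_{tillage}.tsv")
        tree.write(str(outdir / f"tree_{tillage}.nwk"))

        gradients: dict = {}
        for i, substrate in enumerate(truth.substrates):
            per_day = {}
            for j, day in enumerate(cfg.days[substrate]):
                gseed = s_grad + 1000 * i + 10 * j
                ft13 = simulate_gradient(truth, design, "13C", substrate, day,
                                         seed=gseed, gradient_id=f"{tillage}_13C_{substrate}_d{day}")
                ft12 = simulate_gradient(truth, design, "12C", substrate, day,
                                         seed=gseed + 1, gradient_id=f"{tillage}_12C_{substrate}_d{day}")
                per_day[day] = (ft13, ft12)
                for ft in (ft13, ft12):
                    mio.write_count_table(ft.counts, outdir / f"fractions_{ft.gradient_id}.tsv")
            gradients[substrate] = per_day

        all_days = sorted({0} | {d for sub in truth.substrates for d in cfg.days[sub]})
        bulk_counts, dna_yield = simulate_timeseries(
            truth, all_days, total_depth=bulk_depth, seed=s_bulk
        )
        mio.write_count_table(bulk_counts, outdir / f"bulk_counts_{tillage}.tsv")
        dna_yield.to_csv(outdir / f"dna_yield_{tillage}.tsv", sep="\t")

        minser = pd.concat(
            [
                simulate_mineralization(
                    MineralizationTruth(
                        substrate=sub,
                        peak_day=DEFAULT_PEAKS.get(sub, 2.0),
                        total_c=float(total_c.get(sub, 1.6)),
                        shape="pulse" if sub == "xylose" else "logistic",
                    ),
                    timepoints=np.arange(2, 31, 2),
                    tillage=tillage,
                    n_replicates=n_reps,
                    noise_sd=noise_sd,
                    seed=s_min + i,
                )
                for i, sub in enumerate(truth.substrates)
            ],
            ignore_index=True,
        )
        # combined counts + metadata sheet, re-readable by the io module
        meta_rows = []
        frac_frames = []
        for substrate, per_day in gradients.items():
            for day, pair in per_day.items():
                for ft in pair:
                    iso = "13C" if "13C" in ft.gradient_id else "12C"
                    frac_frames.append(ft.counts)
                    for sample in ft.counts.columns:
                        meta_rows.append(
                            {"sample_id": sample, "isotope": iso, "substrate": substrate,
                             "day": day, "tillage": tillage, "replicate": 1,
                             "fraction_bd": ft.fraction_bd[sample], "dna_yield": np.nan}
                        )
        bulk_renamed = bulk_counts.rename(columns=lambda c: f"{tillage}_bulk_{c}")
        for col, day in zip(bulk_renamed.columns, all_days):
            meta_rows.append(
                {"sample_id": col, "isotope": "13C", "substrate": "none",
                 "day": day, "tillage": tillage, "replicate": 1,
                 "fraction_bd": np.nan, "dna_yield": dna_yield.iloc[list(bulk_renamed.columns).index(col)]}
            )
        combined = pd.concat(frac_frames + [bulk_renamed], axis=1)
        mio.write_count_table(combined, outdir / f"counts_all_{tillage}.tsv")
        mio.write_metadata(pd.DataFrame(meta_rows).set_index("sample_id"),
                           outdir / f"metadata_{tillage}.tsv")
        truth.table[["rrn"]].to_csv(outdir / f"rrn_{tillage}.tsv", sep="\t")
        minser.to_csv(outdir / f"mineralization_series_{tillage}.tsv", sep="\t", index=False)

        bundle["tillages"][tillage] = {
            "truth": truth,
            "tree": tree,
            "gradients": gradients,
            "bulk_counts": bulk_counts,
            "dna_yield": dna_yield,
            "rrn": truth.table["rrn"],
            "mineralization": minser,
        }
    return bundle


def _file_inputs(cfg: PipelineConfig) -> dict:
    counts = mio.read_count_table(cfg.counts)
    meta = mio.read_metadata(cfg.metadata)
    rrn = mio.read_rrn(cfg.rrn)
    tree = mio.read_tree(cfg.tree) if cfg.tree else None
    minser = mio.read_mineralization(cfg.mineralization) if cfg.mineralization else None

    bundle: dict = {"tillages": {}}
    for tillage, tmeta in meta.groupby("tillage"):
        frac_meta = tmeta[tmeta.get("fraction_bd").notna()] if "fraction_bd" in tmeta else tmeta.iloc[0:0]
        bulk_meta = tmeta.drop(frac_meta.index)
        gradients: dict = {}
        for (substrate, day), grp in frac_meta.groupby(["substrate", "day"]):
            per = gradients.setdefault(substrate, {})
            pair = []
            for iso in ("13C", "12C"):
                cols = grp.index[grp["isotope"] == iso]
                if len(cols) == 0:
                    raise InvalidDesignError(
                        f"no {iso} fractions for {substrate} day {day} ({tillage})"
                    )
                pair.append(
                    FractionTable(
                        counts=counts[cols],
                        fraction_bd=grp.loc[cols, "fraction_bd"],
                        gradient_id=f"{tillage}_{iso}_{substrate}_d{day}",
                    )
                )
            per[day] = tuple(pair)
        bulk_cols = bulk_meta.index.intersection(counts.columns)
        bulk = counts[bulk_cols]
        day_lookup = bulk_meta.loc[bulk_cols, "day"]
        bulk = bulk.rename(columns=lambda s: f"d{day_lookup[s]:g}")
        dna_yield = pd.Series(
            bulk_meta.loc[bulk_cols, "dna_yield"].to_numpy(),
            index=bulk.columns, name="dna_yield",
        )
        bundle["tillages"][tillage] = {
            "truth": None,
            "tree": tree,
            "gradients": gradients,
            "bulk_counts": bulk,
            "dna_yield": dna_yield,
            "rrn": rrn,
            "mineralization": minser[minser["tillage"] == tillage] if minser is not None else None,
        }
    return bundle


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run every stage and write outputs plus ``manifest.json`` to outdir."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(**config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows = [tuple(w) for w in cfg.windows]

    bundle = _simulated_inputs(cfg, outdir) if cfg.simulate is not None else _file_inputs(cfg)
    s_rarefy = _spawn_seeds(cfg.seed + 104729, 1)[0]

    results: dict = {"tillages": {}}
    trait_frames, window_frames, call_frames = [], [], []
    for tillage, data in bundle["tillages"].items():
        tres: dict = {}

        # mineralization accounting (needed for latency peak days)
        minser = data["mineralization"]
        peaks = dict(DEFAULT_PEAKS)
        if minser is not None:
            cum = cumulative_mineralization(minser)
            rate = mineralization_rate(minser)
            peak_tab = peak_day_summary(minser)
            cum.to_csv(outdir / f"mineralization_cumulative_{tillage}.tsv", sep="\t", index=False)
            rate.to_csv(outdir / f"mineralization_rates_{tillage}.tsv", sep="\t", index=False)
            peak_tab.to_csv(outdir / f"mineralization_peaks_{tillage}.tsv", sep="\t", index=False)
            peaks.update(
                {r.substrate: r.peak_day for r in peak_tab.itertuples() if np.isfinite(r.peak_day)}
            )
            tres["peak_days"] = peaks

        # incorporator identification
        bulk = data["bulk_counts"]
        rarefied = rarefy(bulk, depth=min(cfg.rarefy_depth, int(bulk.sum().min())),
                          seed=s_rarefy)
        from .growth_traits import normalize_table
        normalized = normalize_table(rarefied, data["rrn"], data["dna_yield"])

        for substrate, per_day in data["gradients"].items():
            t13 = {day: [pair[0]] for day, pair in per_day.items()}
            t12 = {day: [pair[1]] for day, pair in per_day.items()}
            calls, wres = mw_hr_sip(
                t13, t12, windows=windows, l2fc_null=cfg.l2fc_null,
                padj_cut=cfg.padj_cut, sparsity_grid=cfg.sparsity_grid,
            )
            wres["substrate"] = substrate
            wres["tillage"] = tillage
            window_frames.append(wres)
            ccopy = calls.reset_index()
            ccopy["substrate"] = substrate
            ccopy["tillage"] = tillage
            call_frames.append(ccopy)
            tres[f"n_incorporators_{substrate}"] = int(calls["is_incorporator"].sum())

            baseline = "d0" if "d0" in normalized.columns else normalized.columns[0]
            traits = build_trait_table(
                calls, wres, normalized, baseline, data["rrn"],
                peak_day=peaks.get(substrate, 0.0),
                substrate=substrate, tillage=tillage,
            )
            trait_frames.append(traits.reset_index())

        results["tillages"][tillage] = tres

    calls_all = pd.concat(call_frames, ignore_index=True)
    calls_all.to_csv(outdir / "incorporators.tsv", sep="\t", index=False)
    windows_all = pd.concat(window_frames, ignore_index=True)
    windows_all.to_csv(outdir / "window_results.tsv", sep="\t", index=False)
    traits_all = pd.concat(trait_frames, ignore_index=True)
    traits_all.to_csv(outdir / "traits.tsv", sep="\t", index=False)

    if traits_all["substrate"].nunique() == 2 and not traits_all.empty:
        comp = compare_groups(
            traits_all, ["rrn", "latency", "max_l2fc", "degree_assimilation"], "substrate"
        )
        comp.to_csv(outdir / "trait_comparisons.tsv", sep="\t", index=False)
        results["trait_comparisons"] = comp.to_dict(orient="records")

    # phylogeny–function distance correlation, per tillage
    if cfg.run_phylofunc:
        for tillage, data in bundle["tillages"].items():
            if data["tree"] is None:
                continue
            sub = traits_all[traits_all["tillage"] == tillage]
            prof = _functional_profiles(sub)
            if prof.shape[0] < 4:
                logger.warning("phylofunc skipped for %s: <4 incorporators", tillage)
                continue
            scaled = scale_traits(prof)
            d_func = functional_distance_matrix(scaled)
            d_phylo = cophenetic_distance(data["tree"], list(prof.index))
            corr = distance_correlation(
                d_phylo, d_func, n_perm=cfg.n_perm,
                seed=_spawn_seeds(cfg.seed + 224737, 1)[0],
            )
            d_func.to_csv(outdir / f"functional_distance_{tillage}.tsv", sep="\t")
            d_phylo.to_csv(outdir / f"phylogenetic_distance_{tillage}.tsv", sep="\t")
            results["tillages"][tillage]["phylofunc"] = corr

    manifest = {
        "package": "mwsip",
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "results": json.loads(json.dumps(results, default=float)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    results["outdir"] = str(outdir)
    return results


def _functional_profiles(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon functional profile: substrate indicators, first label day,
    degree of assimilation (dual incorporators: earliest day, max degree)."""
    if traits.empty:
        return pd.DataFrame()
    rows = {}
    for taxon, grp in traits.groupby("taxon_id"):
        row = {f"substrate_{s}": 0.0 for s in SUBSTRATES}
        for s in grp["substrate"]:
            row[f"substrate_{s}"] = 1.0
        row["first_label_day"] = float(grp["first_label_day"].min())
        row["degree_assimilation"] = float(grp["degree_assimilation"].max())
        rows[taxon] = row
    prof = pd.DataFrame(rows).T
    prof.index.name = "taxon_id"
    return prof.dropna()
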