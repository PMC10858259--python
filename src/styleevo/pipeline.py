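"""Config-driven orchestration of the full analysis.

The polymorphism stage mirrors the study workflow: read a time-calibrated
tree and a binary trait table, fit the four-model grid (equal-rates /
all-rates-different, one or two hidden rate categories), select by AIC,
draw stochastic maps under the best model, and summarise gain/loss counts,
event ages (with density modes) and lineages-through-time by state.  The
correlation stage runs the eight-model Pagel battery per trait pair.

Everything is seeded from the config (no wall-clock seeding) and every
report embeds the config, so identical configs give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import mk_hmm, pagel, stochastic_mapping as smap
from .phylo_core import PhyloTree, node_ages, read_newick_file

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_trait_csv",
    "run_polymorphism_analysis",
    "run_correlation_analysis",
    "report",
]

log = logging.getLogger("styleevo")

DEFAULT_MODEL_GRID = (
    {"constraint": mk_hmm.EQUAL_RATES, "n_hidden": 1},
    {"constraint": mk_hmm.ALL_RATES_DIFFERENT, "n_hidden": 1},
    {"constraint": mk_hmm.EQUAL_RATES, "n_hidden": 2},
    {"constraint": mk_hmm.ALL_RATES_DIFFERENT, "n_hidden": 2},
)

_STATE_ALIASES = {"0": 0, "1": 1, "m": 0, "p": 1}


@dataclass
class PipelineConfig:
    tree: str
    traits: str | None = None
    model_grid: tuple = DEFAULT_MODEL_GRID
    n_maps: int = 100
    seed: int = 0
    root_prior: str = "flat"
    n_restarts: int = 5
    pagel_comparisons: tuple = ()  # ({"name": ..., "traits": csv path}, ...)
    output_dir: str = "styleevo_out"

    def to_dict(self) -> dict:
        return {
            "tree": self.tree,
            "traits": self.traits,
            "model_grid": [dict(g) for g in self.model_grid],
            "n_maps": self.n_maps,
            "seed": self.seed,
            "root_prior": self.root_prior,
            "n_restarts": self.n_restarts,
            "pagel_comparisons": [dict(c) for c in self.pagel_comparisons],
            "output_dir": self.output_dir,
        }


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    cfg = PipelineConfig(
        tree=raw["tree"],
        traits=raw.get("traits"),
        model_grid=tuple(raw.get("model_grid", DEFAULT_MODEL_GRID)),
        n_maps=int(raw.get("n_maps", 100)),
        seed=int(raw["seed"]),
        root_prior=raw.get("root_prior", "flat"),
        n_restarts=int(raw.get("n_restarts", 5)),
        pagel_comparisons=tuple(raw.get("pagel_comparisons", ())),
        output_dir=raw.get("output_dir", "styleevo_out"),
    )
    base = Path(path).parent
    for p in [cfg.tree, cfg.traits] + [c.get("traits") for c in cfg.pagel_comparisons]:
        if p is not None and not (base / p).exists() and not Path(p).exists():
            raise FileNotFoundError(f"config references missing file: {p}")
    return cfg


def read_trait_csv(path, state_column: str = "state") -> dict:
    """Binary trait table ``taxon,state`` with states 0/1 or M/P; empty
    cells are missing (fully ambiguous)."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    taxon_col = cols.get("taxon", df.columns[0])
    st_col = cols.get(state_column, df.columns[1])
    out = {}
    for _, row in df.iterrows():
        raw = row[st_col]
        if pd.isna(raw) or str(raw).strip() == "":
            out[str(row[taxon_col])] = None
            continue
        key = str(raw).strip().casefold()
        if key not in _STATE_ALIASES:
            raise ValueError(f"unrecognised state {raw!r} for taxon {row[taxon_col]!r}")
        out[str(row[taxon_col])] = _STATE_ALIASES[key]
    return out


def _resolve(path, base: Path | None):
    p = Path(path)
    if p.exists() or base is None:
        return p
    return base / path


def run_polymorphism_analysis(
    config: PipelineConfig,
    tree: PhyloTree | None = None,
    tips: dict | None = None,
    base_dir=None,
) -> dict:
    """Fit the model grid, map, and summarise.  ``tree``/``tips`` may be
    passed directly (e.g. from the simulator) to bypass file input."""
    base = Path(base_dir) if base_dir else None
    if tree is None:
        tree = read_newick_file(_resolve(config.tree, base))
    if tips is None:
        if config.traits is None:
            raise ValueError("config has no trait table and none was passed")
        tips = read_trait_csv(_resolve(config.traits, base))

    log.info("polymorphism stage: %d tips", tree.n_tips)
    fits = []
    for i, spec in enumerate(config.model_grid):
        model = mk_hmm.build_model(
            2, int(spec["n_hidden"]), spec["constraint"], config.root_prior
        )
        fit = mk_hmm.fit_ml(
            tree,
            tips,
            model,
            n_restarts=config.n_restarts,
            seed=config.seed + i,
            fill_missing=True,
        )
        if not fit.converged:
            log.warning("model %s did not converge", model.name)
        fits.append(fit)
    table = mk_hmm.model_select(fits)
    best_name = table.iloc[0]["model"]
    best = next(f for f in fits if f.model.name == best_name)
    log.info("best model by AIC: %s", best_name)

    tip_states = [tips[t] for t in tree.tip_labels if tips.get(t) is not None]
    if len(set(tip_states)) < 2:
        log.warning("trait is constant across tips; expect boundary rates "
                    "and event-free maps")

    histories = smap.sample_history(
        tree, tips, best, n_maps=config.n_maps, seed=config.seed + 1000,
        fill_missing=True,
    )
    summary = smap.summarize_maps(histories)
    root_age = float(node_ages(tree).max())

    ages_out = {}
    for name, pair in (("gains", (0, 1)), ("losses", (1, 0))):
        pooled = smap.event_ages(histories, pair, layer="observed")
        single = smap.event_ages(histories[:1], pair, layer="observed")
        entry = {
            "n_events_pooled": int(pooled.size),
            "oldest_single_map": float(single.max()) if single.size else None,
            "youngest_single_map": float(single.min()) if single.size else None,
        }
        entry["mode"] = (
            float(smap.density_mode(pooled, support=(0.0, root_age)))
            if pooled.size >= 2
            else None
        )
        ages_out[name] = entry

    ltt = smap.ltt_by_state(histories[0], layer="observed")
    if best.model.n_hidden > 1:
        ltt_hidden = smap.ltt_by_state(histories[0], layer="hidden")
    else:
        ltt_hidden = None

    bundle = {
        "config": config.to_dict(),
        "model_selection": table,
        "fits": {f.model.name: f for f in fits},
        "best": best,
        "histories": histories,
        "mapping_summary": summary,
        "event_ages": ages_out,
        "ltt_observed": ltt,
        "ltt_hidden": ltt_hidden,
        "root_age": root_age,
    }
    _write_polymorphism_outputs(bundle, config, base)
    return bundle


def _write_polymorphism_outputs(bundle, config: PipelineConfig, base) -> None:
    out = Path(config.output_dir) if base is None else Path(base) / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle["model_selection"].to_csv(out / "model_selection.tsv", sep="\t", index=False)
    (out / "best_fit.json").write_text(bundle["best"].to_json(indent=2, sort_keys=True))
    summary = {
        "config": bundle["config"],
        "mapping": bundle["mapping_summary"].to_dict(),
        "event_ages": bundle["event_ages"],
        "root_age": bundle["root_age"],
    }
    (out / "mapping_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    bundle["ltt_observed"].to_csv(out / "ltt_observed.tsv", sep="\t", index=False)
    if bundle["ltt_hidden"] is not None:
        bundle["ltt_hidden"].to_csv(out / "ltt_hidden.tsv", sep="\t", index=False)
    events = pd.concat(
        [h.to_events_frame() for h in bundle["histories"]], ignore_index=True
    )
    events.to_csv(out / "map_events.tsv", sep="\t", index=False)


def run_correlation_analysis(
    config: PipelineConfig,
    tree: PhyloTree | None = None,
    comparisons: dict | None = None,
    base_dir=None,
) -> dict:
    """Eight-model Pagel battery per configured trait pair.

    ``comparisons`` may map names to ``(x, y)`` tip-state dict pairs to
    bypass file input; otherwise each configured comparison reads a CSV
    with columns ``taxon,x,y``.
    """
    base = Path(base_dir) if base_dir else None
    if tree is None:
        tree = read_newick_file(_resolve(config.tree, base))
    results = {}
    if comparisons is None:
        comparisons = {}
        for comp in config.pagel_comparisons:
            df = pd.read_csv(_resolve(comp["traits"], base))
            x = dict(zip(df["taxon"].astype(str), df["x"]))
            y = dict(zip(df["taxon"].astype(str), df["y"]))
            comparisons[comp["name"]] = (x, y)
    for i, (name, (x, y)) in enumerate(sorted(comparisons.items())):
        log.info("pagel battery: %s", name)
        results[name] = pagel.fit_battery(
            tree, x, y, seed=config.seed + 100 * (i + 1),
            n_restarts=config.n_restarts, root_prior=config.root_prior,
        )
    out = Path(config.output_dir) if base is None else Path(base) / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    payload = {name: r.to_dict() for name, r in results.items()}
    payload["config"] = config.to_dict()
    (out / "pagel_results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    for name, r in results.items():
        r.table.to_csv(out / f"pagel_{name}_ranking.tsv", sep="\t", index=False)
    return {"config": config.to_dict(), "results": results}


def report(bundle: dict) -> str:
    """Human-readable summary; every number also lives in a serialized
    artifact written by the stage that computed it."""
    lines = ["styleevo analysis report", "=" * 26]
    cfg = bundle.get("config", {})
    lines.append(f"seed: {cfg.get('seed')}")
    if "model_selection" in bundle:
        lines.append("\nModel selection (AIC):")
        lines.append(bundle["model_selection"].to_string(index=False))
        s = bundle["mapping_summary"]
        g = s.count_stats("observed", 0, 1)
        l = s.count_stats("observed", 1, 0)
        lines.append(
            f"\nGains of the derived state over {s.n_maps} maps: "
            f"mean {g['mean']:.1f}, median {g['median']:.1f}, "
            f"95% interval [{g['q2.5']:.1f}, {g['q97.5']:.1f}]"
        )
        lines.append(
            f"Losses: mean {l['mean']:.1f}, median {l['median']:.1f}, "
            f"95% interval [{l['q2.5']:.1f}, {l['q97.5']:.1f}]"
        )
        for name in ("gains", "losses"):
            ea = bundle["event_ages"][name]
            if ea["oldest_single_map"] is not None:
                lines.append(
                    f"{name}: oldest {ea['oldest_single_map']:.2f} Myr, "
                    f"youngest {ea['youngest_single_map']:.2f} Myr"
                    + (f", age-density mode {ea['mode']:.2f} Myr" if ea["mode"] else "")
                )
    results = bundle.get("results")
    if results:
        lines.append("\nCorrelated evolution (Pagel batteries):")
        for name, r in results.items():
            lines.append(
                f"  {name}: best {r.best}; {r.verdict} "
                f"(LR={r.lr_statistic:.2f}, df={r.lr_df}, p={r.lr_p:.3g}; "
                f"{r.n_tips_used} shared tips)"
            )
    elif "results" in bundle:
        lines.append("\nNo Pagel comparisons configured; correlation section omitted.")
    return "\n".join(lines) + "\n"
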