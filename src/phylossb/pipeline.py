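"""End-to-end analysis pipeline over subsets, sexes and tree ensembles.

Stage order (each stage writes one report file and is skipped on re-runs if
its report already exists, unless forced):

1. ``signal``       - Fritz-Purvis D per sex and subset
2. ``correlate``    - male vs female SSB correlation LRT across trees
3. ``ancestral``    - marginal ancestral reconstruction export per tree
4. ``simmap``       - stochastic-mapping gain/loss summary
5. ``nodeage``      - node classification vs the reshuffling null + age test
6. ``glm``          - phylogenetic logistic regressions (Table-1 shape)
7. ``directional``  - four-model Pagel comparison (Table-2 shape)

Regressions and directional tests pair each sex's SSB with the same sex's
adulticide.  A manifest (config, seeds, versions, wall-times, report paths)
makes a run reproducible from config + seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mk import fit_mk, marginal_ancestral_states
from .nodeage import classify_nodes_vs_null, compare_age_distributions
from .pagel import compare_models, correlation_test, fit_all_pagel_models
from .phyloglm import collinearity_diagnostics, fit_phylo_logistic
from .signal import d_statistic
from .simmap import sample_histories, transition_counts_summary
from .simulate import jitter_tree_ensemble, make_fixture_dataset
from .traits import TraitTable, apply_subset, load_trait_table, summarize_prevalence
from .trees import TreeEnsemble, read_tree_ensemble

log = logging.getLogger("phylossb.pipeline")

STAGES = ("signal", "correlate", "ancestral", "simmap", "nodeage", "glm", "directional")


@dataclass
class PipelineConfig:
    """Fully serializable run configuration."""

    out_dir: str = "phylossb_run"
    trees: str | None = None           # Newick path; None -> synthetic
    traits: str | None = None          # CSV path; None -> synthetic
    synthetic: dict = field(default_factory=lambda: {"n_species": 300})
    subsets: list[str] = field(default_factory=lambda: ["I"])
    sexes: list[str] = field(default_factory=lambda: ["male", "female"])
    seed: int = 0
    n_trees_signal: int = 3
    n_trees_correlation: int = 2
    n_trees_ancestral: int = 3
    n_trees_directional: int = 2
    n_permutations: int = 200
    n_simulations: int = 200
    n_shuffles: int = 25
    n_simmap: int = 200
    n_boot: int = 25
    citation_threshold: int = 1000
    nodeage_refit: bool = False        # fast mode by default in the pipeline
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _ssb_map(table: TraitTable, sex: str) -> dict[str, int]:
    return table.binary_map(f"{sex}_ssb")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(2**31)) for s in STAGES}

    # ------------------------------------------------------------- inputs
    if config.traits is not None and config.trees is None:
        raise ValueError("a traits file requires a trees file; synthetic trees "
                         "are only generated together with synthetic traits")
    if config.traits is not None:
        table = load_trait_table(config.traits)
    else:
        dataset = make_fixture_dataset(seed=config.seed, **config.synthetic)
        table = dataset.trait_table(provenance=f"synthetic(seed={config.seed})")
    if config.trees is not None:
        ensemble = read_tree_ensemble(config.trees)
    else:
        n_needed = max(config.n_trees_signal, config.n_trees_correlation,
                       config.n_trees_ancestral, config.n_trees_directional)
        ensemble = jitter_tree_ensemble(dataset.tree, n_needed, seed=config.seed + 1)

    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": stage_seeds,
        "n_trees": len(ensemble),
        "n_species": len(table),
        "reports": {},
        "skipped": [],
        "wall_times": {},
    }

    subset_tables = {
        s: apply_subset(table, s, config.citation_threshold) for s in config.subsets
    }
    prev = summarize_prevalence(table).to_frame()
    prev_path = out / "prevalence.csv"
    prev.to_csv(prev_path, index=False)
    manifest["reports"]["prevalence"] = str(prev_path)

    def stage(name: str):
        path = out / f"{name}.csv"

        def decorator(fn):
            t0 = time.time()
            if path.exists() and not config.force:
                log.info("stage %s: report exists, skipping", name)
                manifest["skipped"].append(name)
                manifest["reports"][name] = str(path)
                return
            try:
                df = fn(stage_seeds[name])
            except Exception:
                log.exception("stage %s failed", name)
                raise
            df.to_csv(path, index=False)
            manifest["reports"][name] = str(path)
            manifest["wall_times"][name] = round(time.time() - t0, 3)
            log.info("stage %s done in %.1fs", name, time.time() - t0)

        return decorator

    # ------------------------------------------------------------- stages
    @stage("signal")
    def _signal(seed):
        rows = []
        srng = np.random.default_rng(seed)
        for subset_id, tab in subset_tables.items():
            for sex in config.sexes:
                states = _ssb_map(tab, sex)
                for k, tree in enumerate(ensemble.subsample(config.n_trees_signal)):
                    sub, _ = tree.prune_to_taxa(set(states) & set(tree.tip_labels))
                    st = {s: states[s] for s in sub.tip_labels}
                    res = d_statistic(sub, st, config.n_permutations,
                                      config.n_simulations, seed=int(srng.integers(2**31)))
                    rows.append({"subset": subset_id, "trait": f"{sex}_ssb",
                                 "tree": k, "D": res.D, "d_obs": res.d_obs,
                                 "p_random": res.p_random, "p_brownian": res.p_brownian})
        return pd.DataFrame(rows)

    @stage("correlate")
    def _correlate(seed):
        rows = []
        srng = np.random.default_rng(seed)
        for subset_id, tab in subset_tables.items():
            xm = _ssb_map(tab, "male")
            ym = _ssb_map(tab, "female")
            for k, tree in enumerate(ensemble.subsample(config.n_trees_correlation)):
                sub, _ = tree.prune_to_taxa(set(xm) & set(ym) & set(tree.tip_labels))
                ct = correlation_test(sub, xm, ym, seed=int(srng.integers(2**31)),
                                      n_restarts=1)
                rows.append({"subset": subset_id, "tree": k, "chi2": ct.chi2,
                             "df": ct.df, "p": ct.p_value,
                             "lnL_uncorrelated": ct.log_likelihood_uncorrelated,
                             "lnL_correlated": ct.log_likelihood_correlated})
        return pd.DataFrame(rows)

    @stage("ancestral")
    def _ancestral(seed):
        frames = []
        srng = np.random.default_rng(seed)
        for subset_id, tab in subset_tables.items():
            for sex in config.sexes:
                states = _ssb_map(tab, sex)
                for k, tree in enumerate(ensemble.subsample(config.n_trees_ancestral)):
                    sub, _ = tree.prune_to_taxa(set(states) & set(tree.tip_labels))
                    st = {s: states[s] for s in sub.tip_labels}
                    fit = fit_mk(sub, st, "ARD", n_restarts=2,
                                 seed=int(srng.integers(2**31)))
                    rec = marginal_ancestral_states(sub, st, fit, tree_id=k)
                    df = rec.to_frame()
                    df.insert(0, "subset", subset_id)
                    df.insert(1, "trait", f"{sex}_ssb")
                    frames.append(df)
        return pd.concat(frames, ignore_index=True)

    @stage("simmap")
    def _simmap(seed):
        rows = []
        srng = np.random.default_rng(seed)
        for subset_id, tab in subset_tables.items():
            for sex in config.sexes:
                states = _ssb_map(tab, sex)
                tree = ensemble[0]
                sub, _ = tree.prune_to_taxa(set(states) & set(tree.tip_labels))
                st = {s: states[s] for s in sub.tip_labels}
                fit = fit_mk(sub, st, "ARD", n_restarts=2,
                             seed=int(srng.integers(2**31)))
                hs = sample_histories(sub, st, fit, n=config.n_simmap,
                                      seed=int(srng.integers(2**31)))
                summ = transition_counts_summary(hs)
                rows.append({"subset": subset_id, "trait": f"{sex}_ssb",
                             "n_iterations": summ.n_iterations,
                             "mean_gains": summ.mean_gains,
                             "mean_losses": summ.mean_losses,
                             "sd_gains": summ.sd_gains, "sd_losses": summ.sd_losses,
                             "gains_q2.5": summ.q_gains[0], "gains_q97.5": summ.q_gains[1],
                             "losses_q2.5": summ.q_losses[0], "losses_q97.5": summ.q_losses[1]})
        return pd.DataFrame(rows)

    @stage("nodeage")
    def _nodeage(seed):
        rows = []
        srng = np.random.default_rng(seed)
        for subset_id, tab in subset_tables.items():
            for sex in config.sexes:
                states = _ssb_map(tab, sex)
                tree = ensemble[0]
                sub, _ = tree.prune_to_taxa(set(states) & set(tree.tip_labels))
                st = {s: states[s] for s in sub.tip_labels}
                cls = classify_nodes_vs_null(
                    sub, np.array([st[l] for l in sub.tip_labels]),
                    n_shuffles=config.n_shuffles, refit=config.nodeage_refit,
                    seed=int(srng.integers(2**31)))
                comp = compare_age_distributions(cls)
                row = {"subset": subset_id, "trait": f"{sex}_ssb",
                       "n_present": comp.n_present, "n_absent": comp.n_absent,
                       "n_equivocal": sum(1 for c in cls if c.label == "equivocal")}
                row.update({k: v for k, v in comp.to_dict().items()
                            if k not in ("n_present", "n_absent")})
                rows.append(row)
        return pd.DataFrame(rows)

    @stage("glm")
    def _glm(seed):
        rows = []
        srng = np.random.default_rng(seed)
        for subset_id, tab in subset_tables.items():
            for sex in config.sexes:
                resp = _ssb_map(tab, sex)
                df = tab.data.set_index("species")
                cols = {"sociality": "sociality",
                        "adulticide": f"adulticide_{sex}"}
                pred = pd.DataFrame({
                    name: df[col] for name, col in cols.items()
                }).dropna()
                pred["log_citations"] = np.log1p(df.loc[pred.index, "citations"])
                tree = ensemble[0]
                keep = [s for s in pred.index if s in resp and s in tree.tip_index]
                pred = pred.loc[keep]
                sub, _ = tree.prune_to_taxa(keep)
                try:
                    diag = collinearity_diagnostics(pred)
                    fit = fit_phylo_logistic(sub, resp, pred, n_boot=config.n_boot,
                                             seed=int(srng.integers(2**31)))
                except ValueError as exc:
                    log.warning("glm %s/%s skipped: %s", subset_id, sex, exc)
                    continue
                for name, est in fit.coefficients.items():
                    rows.append({
                        "subset": subset_id, "response": f"{sex}_ssb", "term": name,
                        "estimate": est,
                        "ci_lower": fit.ci_lower[name] if fit.ci_lower is not None else np.nan,
                        "ci_upper": fit.ci_upper[name] if fit.ci_upper is not None else np.nan,
                        "p_boot": fit.p_values[name] if fit.p_values is not None else np.nan,
                        "alpha": fit.alpha, "n": fit.n_obs,
                        "separation": fit.separation,
                        "max_vif": float(diag.vif.max()),
                    })
        return pd.DataFrame(rows)

    @stage("directional")
    def _directional(seed):
        frames = []
        srng = np.random.default_rng(seed)
        for subset_id, tab in subset_tables.items():
            for sex in config.sexes:
                resp = _ssb_map(tab, sex)
                for partner in ("sociality", f"adulticide_{sex}"):
                    x = tab.binary_map(partner)
                    fits = []
                    for k, tree in enumerate(ensemble.subsample(config.n_trees_directional)):
                        sub, _ = tree.prune_to_taxa(
                            set(resp) & set(x) & set(tree.tip_labels))
                        try:
                            fits.append(fit_all_pagel_models(
                                sub, x, resp, n_restarts=1,
                                seed=int(srng.integers(2**31)), tree_id=k))
                        except ValueError as exc:
                            log.warning("directional %s/%s/%s tree %d skipped: %s",
                                        subset_id, sex, partner, k, exc)
                    if not fits:
                        continue
                    comp = compare_models(fits)
                    df = comp.to_frame()
                    df.insert(0, "subset", subset_id)
                    df.insert(1, "response", f"{sex}_ssb")
                    df.insert(2, "partner", partner)
                    frames.append(df)
        return pd.concat(frames, ignore_index=True)

    manifest["checksums"] = {
        name: _checksum(Path(p)) for name, p in manifest["reports"].items()
    }
    manifest["total_wall_time"] = round(time.time() - t_start, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
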