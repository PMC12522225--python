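"""End-to-end screening workflow.

Orchestrates the full analysis the package implements: cohort splitting
into train/validation/test, a baseline-comparability report across the
splits, the three model recipes fitted on the training split, operating
thresholds fixed by the Youden index on the validation split, and final
screening evaluation — AUCs with DeLong CIs, paired DeLong comparisons
of every model/marker against the combined and protein models, and
sensitivity/specificity tables — on the held-out test split.

No information flows from validation or test rows into any fitted state:
every fit receives the training subset only, the validation split fixes
thresholds, and the test split is touched exactly once.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, simulate
from .motifs import counts_to_ratios

logger = logging.getLogger("motifscreen")

SPLITS = ("train", "validation", "test")


@dataclass
class SplitConfig:
    """Train/validation/test fractions (defaults 0.49/0.21/0.30) with
    optional stratification (default: by clinical subgroup)."""

    fractions: tuple = (0.49, 0.21, 0.30)
    seed: int = 0
    stratify_by: str | None = "subgroup"

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if len(f) != 3 or np.any(f <= 0) or np.any(f >= 1):
            raise ValueError("need three fractions in (0, 1)")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def allocate_split_sizes(n: int, fractions) -> tuple[int, ...]:
    """Integer split sizes for ``n`` samples.

    Every split but the last receives floor(n * fraction); the last split
    absorbs the rounding remainder (so 491 at 0.49/0.21/0.30 gives
    240/103/148).
    """
    fractions = np.asarray(fractions, dtype=float)
    sizes = [int(np.floor(n * f)) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    if sizes[-1] < 0:
        raise ValueError("fractions allocate more samples than available")
    return tuple(sizes)


def split_cohort(meta: pd.DataFrame, config: SplitConfig | None = None) -> pd.DataFrame:
    """Assign each sample to train/validation/test.

    The partition is disjoint and exhaustive and deterministic under the
    seed.  With stratification on, sizes are allocated within each
    stratum; strata smaller than 3 fall back to the global pool with a
    warning.
    """
    config = config or SplitConfig()
    rng = np.random.default_rng(config.seed)
    meta = meta.copy()
    assignment = pd.Series("", index=meta.index, dtype=object)

    def assign(indices) -> None:
        indices = np.asarray(indices)
        perm = rng.permutation(len(indices))
        sizes = allocate_split_sizes(len(indices), config.fractions)
        start = 0
        for split, size in zip(SPLITS, sizes):
            assignment.iloc[indices[perm[start : start + size]]] = split
            start += size

    if config.stratify_by is None:
        assign(np.arange(len(meta)))
    else:
        if config.stratify_by not in meta.columns:
            raise ValueError(f"stratification column {config.stratify_by!r} absent")
        pooled = []
        for _, idx in meta.groupby(config.stratify_by, sort=True).indices.items():
            if len(idx) < 3:
                logger.warning(
                    "stratum of size %d < 3: assigned by global draw", len(idx)
                )
                pooled.extend(idx.tolist())
            else:
                assign(idx)
        if pooled:
            assign(pooled)
    meta["split"] = assignment.to_numpy()
    return meta


def baseline_report(meta: pd.DataFrame) -> pd.DataFrame:
    """Comparability of clinical covariates across the three splits.

    Categorical covariates get a split cross-tabulation with a Pearson
    chi-square; numeric covariates get median (IQR) per split with a
    Kruskal-Wallis test.  Covariates absent from the table are skipped
    with a note row.
    """
    if not set(meta["split"]) <= set(SPLITS) or (meta["split"] == "").any():
        raise ValueError("splits must be assigned before the baseline report")
    categorical = ["sex", "smoking", "drinking", "group", "subgroup"]
    numeric = ["age"]
    rows = []
    for cov in numeric:
        if cov not in meta.columns:
            rows.append({"covariate": cov, "type": "missing", "note": "skipped"})
            continue
        h, p = evaluate.kruskal_wallis(meta[cov].to_numpy(), meta["split"].to_numpy())
        summary = {
            split: f"{meta.loc[meta['split'] == split, cov].median():.0f} "
            f"({meta.loc[meta['split'] == split, cov].quantile(0.25):.0f}, "
            f"{meta.loc[meta['split'] == split, cov].quantile(0.75):.0f})"
            for split in SPLITS
        }
        rows.append(
            {
                "covariate": cov,
                "type": "numeric",
                "statistic": h,
                "p": p,
                **summary,
            }
        )
    for cov in categorical:
        if cov not in meta.columns:
            rows.append({"covariate": cov, "type": "missing", "note": "skipped"})
            continue
        table = pd.crosstab(meta[cov], meta["split"])[list(SPLITS)]
        if (table.to_numpy().sum(axis=1) == 0).any() or table.shape[0] < 2:
            rows.append({"covariate": cov, "type": "categorical", "note": "degenerate"})
            continue
        chi2, df, p = evaluate.chisq_independence(table.to_numpy())
        rows.append(
            {
                "covariate": cov,
                "type": "categorical",
                "statistic": chi2,
                "df": df,
                "p": p,
                **{
                    split: "; ".join(
                        f"{level}={table.loc[level, split]}" for level in table.index
                    )
                    for split in SPLITS
                },
            }
        )
    return pd.DataFrame(rows)


class _stage:
    """Context manager naming the pipeline stage in any failure, so an
    aborted run reports where it stopped (partial artefacts are retained
    by the caller)."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, _StageError):
            raise _StageError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        return False


class _StageError(RuntimeError):
    pass


def _finite_threshold(t: float, observed) -> float:
    """Youden optima at the ∓inf sentinels (no-discrimination degenerate
    cases, e.g. constant scores) are clamped to the observed score range so
    screening reports stay well defined with identical calls."""
    if np.isfinite(t):
        return float(t)
    observed = np.asarray(observed, dtype=float)
    return float(observed.min()) if t == -np.inf else float(observed.max() + 1.0)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """One end-to-end run: simulation conditions (when no input files are
    given), analysis settings, and output location."""

    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    alpha: float = 0.05
    n_components: int = 30
    n_folds: int = 10
    n_trees: int = 500
    rfe_step: int = 1
    recipes: tuple = ("motif", "protein", "combined")
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Fan one root seed out to fixed per-stage streams (< 2**31)."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


def case_labels(meta: pd.DataFrame) -> np.ndarray:
    """1 for ESPL/ESCC samples, 0 for controls."""
    return (meta["group"] != "control").astype(int).to_numpy()


MARKER_PANEL = list(classify.PROTEIN_FEATURES)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    motif_counts: pd.DataFrame | None = None,
    proteins: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
) -> dict:
    """Execute the full screening analysis and return the result bundle.

    With no input tables, a synthetic cohort is generated from
    ``config.simulation`` (reseeded from the root seed).  Returns a dict
    with the fitted models, thresholds, per-split scores, the test-set
    comparison table (models and single markers vs the combined and
    protein models, paired DeLong tests), screening reports, and the run
    manifest.  When ``out_dir`` is given, all tables and the manifest are
    written as TSV/JSON.
    """
    cfg = config
    results: dict = {"config": cfg}

    if meta is None:
        with _stage("simulate"):
            sim = simulate.SimulationConfig(
                **{
                    **{
                        k: getattr(cfg.simulation, k)
                        for k in (
                            "n_per_subgroup",
                            "n_up_motifs",
                            "n_down_motifs",
                            "effect_delta",
                            "severity_scaling",
                            "dirichlet_concentration",
                            "fragments_mean",
                            "fragments_dispersion",
                            "protein_params",
                        )
                    },
                    "seed": cfg.stage_seed("simulate"),
                }
            )
            logger.info(
                "simulating cohort (%d samples)", sum(sim.n_per_subgroup.values())
            )
            meta = simulate.generate_metadata(sim)
            motif_counts, ground_truth = simulate.generate_motif_counts(meta, sim)
            proteins = simulate.generate_protein_panel(meta, sim)
            results["ground_truth"] = ground_truth
            results["simulation"] = sim
    if motif_counts is None or proteins is None:
        raise ValueError("need both a motif source and a protein table")

    with _stage("normalise"):
        ratios = counts_to_ratios(motif_counts)
        meta = meta.set_index("sample_id", drop=False).loc[ratios.index]
        proteins = proteins.loc[ratios.index]

    with _stage("split"):
        split_cfg = SplitConfig(
            fractions=cfg.split.fractions,
            seed=cfg.stage_seed("split"),
            stratify_by=cfg.split.stratify_by,
        )
        meta = split_cohort(meta.reset_index(drop=True), split_cfg)
        meta = meta.set_index("sample_id", drop=False)
        results["meta"] = meta
        results["ratios"] = ratios
        results["proteins"] = proteins
        results["baseline"] = baseline_report(meta)

    with _stage("assemble-features"):
        missing = [m for m in MARKER_PANEL if m not in proteins.columns]
        if missing:
            raise ValueError(f"protein table missing marker columns: {missing}")
        layer = pd.concat([ratios, proteins[MARKER_PANEL]], axis=1)
        layer_for = {
            "motif": ratios,
            "protein": proteins[MARKER_PANEL],
            "combined": layer,
        }
        idx = {s: meta.index[meta["split"] == s] for s in SPLITS}
        y = {s: case_labels(meta.loc[idx[s]]) for s in SPLITS}

    models, thresholds, scores = {}, {}, {}
    for recipe in cfg.recipes:
        with _stage(f"fit:{recipe}"):
            logger.info(
                "fitting %s recipe on %d training samples", recipe, len(idx["train"])
            )
            X = layer_for[recipe]
            model = classify.build_recipe(
                recipe,
                X.loc[idx["train"]],
                y["train"],
                alpha=cfg.alpha,
                n_components=cfg.n_components,
                n_folds=cfg.n_folds,
                n_trees=cfg.n_trees,
                rfe_step=cfg.rfe_step,
                seed=cfg.stage_seed(f"fit:{recipe}"),
            )
            models[recipe] = model
            scores[recipe] = {s: model.predict_scores(X.loc[idx[s]]) for s in SPLITS}
            t, _ = evaluate.youden_threshold(
                scores[recipe]["validation"], y["validation"]
            )
            thresholds[recipe] = _finite_threshold(t, scores[recipe]["validation"])
    results["models"] = models
    results["thresholds"] = thresholds
    results["scores"] = scores

    # marker rules: direction high-is-positive, thresholds from the
    # validation split by Youden, same machinery as the models
    marker_thresholds = {}
    for marker in MARKER_PANEL:
        vals = proteins.loc[idx["validation"], marker].to_numpy()
        t, _ = evaluate.youden_threshold(vals, y["validation"])
        marker_thresholds[marker] = _finite_threshold(t, vals)
    results["marker_thresholds"] = marker_thresholds

    # test-set evaluation
    with _stage("evaluate"):
        test_meta = meta.loc[idx["test"]]
        y_test = y["test"]
        comparison_rows = []
        screening = {}
        test_scores: dict[str, np.ndarray] = {}
        for recipe in cfg.recipes:
            test_scores[recipe] = scores[recipe]["test"]
        for marker in MARKER_PANEL:
            test_scores[marker] = proteins.loc[idx["test"], marker].to_numpy()

        for name, s in test_scores.items():
            est = evaluate.delong_ci(s, y_test)
            threshold = thresholds.get(name, marker_thresholds.get(name))
            report = evaluate.screening_metrics(s, test_meta, threshold)
            screening[name] = report
            row = {
                "model": name,
                "sensitivity": report.sensitivity.percent,
                "sens_ci": f"{report.sensitivity.ci_lower_percent:.1f}-"
                f"{report.sensitivity.ci_upper_percent:.1f}",
                "specificity": report.specificity.percent,
                "spec_ci": f"{report.specificity.ci_lower_percent:.1f}-"
                f"{report.specificity.ci_upper_percent:.1f}",
                "auc": est.auc,
                "auc_ci_lower": est.ci_lower,
                "auc_ci_upper": est.ci_upper,
                "threshold": threshold,
            }
            for ref in ("combined", "protein"):
                if ref in test_scores:
                    cmp = evaluate.delong_paired_test(s, test_scores[ref], y_test)
                    row[f"p_vs_{ref}"] = cmp.p
            comparison_rows.append(row)
    results["comparison"] = pd.DataFrame(comparison_rows)
    results["screening"] = screening
    results["roc"] = {
        recipe: evaluate.roc_curve_points(test_scores[recipe], y_test)
        for recipe in cfg.recipes
    }

    if out_dir is not None:
        with _stage("write"):
            results["manifest"] = _write_outputs(results, Path(out_dir))
    return results


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(results: dict, out_dir: Path) -> dict:
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    cfg: PipelineConfig = results["config"]
    paths = {}

    def save(name: str, frame: pd.DataFrame, index=False) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=index)
        paths[name] = str(path)

    save("metadata.tsv", results["meta"], index=False)
    save("baseline_report.tsv", results["baseline"])
    save("comparison_test_set.tsv", results["comparison"])
    for recipe, model in results["models"].items():
        save(
            f"importances_{recipe}.tsv",
            model.feature_importances_.rename("importance")
            .rename_axis("feature")
            .reset_index(),
        )
        trace = pd.DataFrame(
            sorted(model.rfe_.cv_scores.items()), columns=["subset_size", "mean_cv_auc"]
        )
        save(f"rfe_trace_{recipe}.tsv", trace)
    for name, report in results["screening"].items():
        save(f"screening_{name}.tsv", report.to_frame())
    for recipe, curve in results.get("roc", {}).items():
        save(
            f"roc_{recipe}.tsv",
            pd.DataFrame(
                {
                    "threshold": curve.thresholds,
                    "sensitivity": curve.sensitivity,
                    "specificity": curve.specificity,
                }
            ),
        )
    for recipe in ("motif", "combined"):
        model = results["models"].get(recipe)
        if model is not None and hasattr(model, "selector_"):
            save(
                f"differential_motifs_{recipe}.tsv",
                model.selector_.result_.rename_axis("motif").reset_index(),
            )
        if model is not None and hasattr(model, "pca_"):
            loadings = pd.DataFrame(
                model.pca_.components_,
                index=[f"PC{i + 1}" for i in range(model.pca_.n_components_)],
                columns=model.selector_.selected_features_,
            )
            save(f"pca_loadings_{recipe}.tsv", loadings.rename_axis("component"), index=True)
    confusion = pd.DataFrame(
        [
            {"model": name, **report.confusion}
            for name, report in results["screening"].items()
        ]
    )
    save("confusion_test_set.tsv", confusion)
    import joblib

    for recipe, model in results["models"].items():
        archive = out_dir / f"model_{recipe}.joblib"
        joblib.dump(model, archive)
        paths[archive.name] = str(archive)

    manifest = {
        "software_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {
            stage: cfg.stage_seed(stage)
            for stage in ["simulate", "split"] + [f"fit:{r}" for r in cfg.recipes]
        },
        "thresholds": {k: float(v) for k, v in results["thresholds"].items()},
        "marker_thresholds": {
            k: float(v) for k, v in results["marker_thresholds"].items()
        },
        "selected_features": {
            r: m.selected_features_ for r, m in results["models"].items()
        },
        "published_feature_counts": classify.PUBLISHED_FEATURE_COUNTS,
        "config": {
            "alpha": cfg.alpha,
            "n_components": cfg.n_components,
            "n_folds": cfg.n_folds,
            "n_trees": cfg.n_trees,
            "rfe_step": cfg.rfe_step,
            "split_fractions": list(cfg.split.fractions),
            "stratify_by": cfg.split.stratify_by,
        },
        "artefacts": {},
    }
    for name, path in paths.items():
        manifest["artefacts"][name] = {"path": path, "sha256": _digest(Path(path))}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["path"] = str(manifest_path)
    return manifest
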