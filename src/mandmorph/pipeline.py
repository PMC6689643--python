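"""End-to-end analysis pipeline.

Order of stages follows the study design: superimpose everything, screen
for outliers on Procrustes distances to the mean, re-superimpose the
retained specimens, summarize symmetric shape by PCA, fit the Bayesian
mixed models (a focal full model against a reduced model without the focal
predictors, for size and for shape), compare them by WAIC, and finish with
the effect-vector geometry and the shape score for the focal effect.

Two standard analyses are built in: the captivity test (all specimens;
focal predictor ``captivity``) and the ecogeography test (wild-caught
specimens only; focal predictors ``temperature`` and ``precipitation``).
Robustness variants — size-adjusted shape responses, an island covariate,
age-filtered or adults-only subsets — are configuration switches over the
same code path.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import blmm, effect_geometry, screening, shape_space, superimpose, synthgen
from .landmark_io import JoinedDataset, join_dataset, read_landmarks, read_metadata
from .scheme import mandible_scheme

__all__ = ["PipelineConfig", "PipelineResult", "subset", "build_model_table", "run"]


@dataclass
class PipelineConfig:
    """One self-contained pipeline run.

    Either ``landmarks``/``metadata`` paths or a ``simulate`` block (keyword
    arguments of :class:`mandmorph.synthgen.GeneratorConfig`) must be given.
    """

    landmarks: Optional[str] = None
    metadata: Optional[str] = None
    simulate: Optional[dict] = None
    alpha: float = 0.05
    iterative_screen: bool = False
    n_pcs: int = 10
    tangent: bool = True
    size_adjusted: bool = False
    island_covariate: bool = False
    adults_only: bool = False
    exclude_captive_age_over: Optional[float] = None
    analyses: tuple[str, ...] = ("captivity",)  # and/or "ecogeography"
    chains: int = 4
    iterations: int = 10_000
    burn_in: int = 5_000
    seed: int = 0
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)


@dataclass
class PipelineResult:
    screening_report: dict
    pca_diagnostic: dict
    model_table: pd.DataFrame
    summaries: dict[str, blmm.FitSummary]
    comparisons: dict[str, pd.DataFrame]
    geometry: pd.DataFrame
    shape_scores: pd.DataFrame
    log: dict


def subset(data: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply the configured specimen filters.

    ``adults_only`` keeps fully erupted third molars (age_class == 1).
    ``exclude_captive_age_over`` drops captive specimens older than the
    threshold; wild specimens (unknown age) are always kept.
    """
    out = data
    if config.adults_only:
        out = out[out["age_class"] == 1]
    if config.exclude_captive_age_over is not None:
        if "age_years" not in out.columns or out.loc[out["captivity"] > 0, "age_years"].isna().all():
            raise ValueError(
                "exclude_captive_age_over needs an age_years column for captives"
            )
        thresh = float(config.exclude_captive_age_over)
        drop = (out["captivity"] > 0) & (out["age_years"] > thresh)
        out = out[~drop]
    return out.reset_index(drop=True)


_ANALYSES = {
    # label: (focal predictors, base predictors, wild_only)
    "captivity": (["captivity"], ["sex", "age_class"], False),
    "ecogeography": (["temperature", "precipitation"], ["sex", "age_class"], True),
}


def build_model_table(
    dataset: JoinedDataset,
    aligned: superimpose.AlignedShapeSet,
    scores: np.ndarray,
) -> pd.DataFrame:
    """Assemble the modelling table: PC scores, log centroid size ("size")
    and the covariates, one row per retained specimen."""
    table = dataset.metadata.copy().reset_index(drop=True)
    table["size"] = aligned.log_centroid_size
    for j in range(scores.shape[1]):
        table[f"PC{j + 1}"] = scores[:, j]
    return table


def _superimpose_retained(
    dataset: JoinedDataset, keep_ids: Optional[set] = None
) -> tuple[JoinedDataset, superimpose.AlignedShapeSet]:
    if keep_ids is not None:
        configs = [c for c in dataset.configs if c.specimen_id in keep_ids]
        meta = dataset.metadata[
            dataset.metadata["specimen_id"].isin(keep_ids)
        ].reset_index(drop=True)
        dataset = JoinedDataset(configs=configs, metadata=meta)
    return dataset, superimpose.gpa(dataset.configs)


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; writes a report bundle when ``outdir`` is
    set.  Raises with the failing stage's name on error."""
    stage = "input"
    try:
        scheme = mandible_scheme()
        if config.simulate is not None:
            gen = synthgen.GeneratorConfig(**{"seed": config.seed, **config.simulate})
            synth = synthgen.generate(gen, scheme)
            dataset = join_dataset(synth.configs, synth.metadata)
        elif config.landmarks and config.metadata:
            configs = read_landmarks(config.landmarks, scheme)
            meta = read_metadata(config.metadata)
            dataset = join_dataset(configs, meta)
        else:
            raise ValueError("config needs either file paths or a simulate block")

        stage = "superimpose"
        aligned = superimpose.gpa(dataset.configs)

        stage = "screening"
        report = screening.grubbs_screen(
            aligned.distances_to_mean("aligned"),
            dataset.specimen_ids,
            alpha=config.alpha,
            iterative=config.iterative_screen,
        )
        if report.outlier_ids:
            keep = set(dataset.specimen_ids) - set(report.outlier_ids)
            dataset, aligned = _superimpose_retained(dataset, keep)

        stage = "pca"
        shapes = aligned.flat("symmetric", tangent=config.tangent)
        size_adjust_info = None
        if config.size_adjusted:
            shapes, r2, p = shape_space.size_adjust(
                shapes, aligned.log_centroid_size, seed=config.seed
            )
            size_adjust_info = {"r2": r2, "p": p}
        pca = shape_space.fit_pca(shapes)
        m = min(config.n_pcs, pca.rank)
        scores, diagnostic = shape_space.retain(pca, m)
        if size_adjust_info:
            diagnostic["size_adjust"] = size_adjust_info

        stage = "subset"
        table_all = build_model_table(dataset, aligned, scores)
        table_all = subset(table_all, config)

        stage = "fit"
        pc_names = [f"PC{j + 1}" for j in range(m)]
        summaries: dict[str, blmm.FitSummary] = {}
        comparisons: dict[str, pd.DataFrame] = {}
        fits: dict[str, blmm.PosteriorDraws] = {}
        for analysis in config.analyses:
            focal, base, wild_only = _ANALYSES[analysis]
            table = table_all[table_all["captivity"] == 0] if wild_only else table_all
            table = table.reset_index(drop=True)
            extra = ["island"] if config.island_covariate else []
            for resp_label, responses, base_extra in (
                ("size", ["size"], []),
                ("shape", pc_names, ["size"]),
            ):
                full_fx = base_extra + base + extra + focal
                red_fx = base_extra + base + extra
                variant_fits = []
                for kind, fx in (("full", full_fx), ("reduced", red_fx)):
                    spec = blmm.ModelSpec(
                        responses=responses,
                        fixed_effects=fx,
                        chains=config.chains,
                        iterations=config.iterations,
                        burn_in=config.burn_in,
                        seed=config.seed,
                    )
                    label = f"{analysis}_{resp_label}_{kind}"
                    draws = blmm.fit(table, spec)
                    fits[label] = draws
                    summaries[label] = blmm.summarize(draws)
                    variant_fits.append((label, draws))
                comparisons[f"{analysis}_{resp_label}"] = blmm.compare(variant_fits)

        stage = "effect_geometry"
        geometry_rows: list[dict] = []
        score_frame = pd.DataFrame()
        # element-wise vector correlations need at least 3 shape variables
        if "captivity" in config.analyses and m >= 3:
            shape_full = fits["captivity_shape_full"]
            vectors = {
                p: effect_geometry.effect_vector(shape_full, p)
                for p in shape_full.predictor_names
            }
            preds = list(vectors)
            for i, a in enumerate(preds):
                for b in preds[i + 1 :]:
                    for mode in ("within", "between"):
                        res = effect_geometry.compare_effects(
                            vectors[a], vectors[b], mode=mode
                        )
                        geometry_rows.append(
                            {k: v for k, v in res.items() if not isinstance(v, np.ndarray)}
                        )

            stage = "shape_score"
            cap = vectors["captivity"]
            spec_std, _ = blmm.standardize(
                table_all.reset_index(drop=True), pc_names
            )
            y = spec_std[pc_names].to_numpy()
            score = effect_geometry.shape_score(y, cap.beta_mean)
            score_frame = pd.DataFrame(
                {
                    "specimen_id": table_all["specimen_id"].to_numpy(),
                    "shape_score": score.scores,
                    "captivity": table_all["captivity"].to_numpy(),
                }
            )
            for axis in range(min(4, m)):
                r, p = effect_geometry.score_axis_correlation(
                    score, table_all[f"PC{axis + 1}"].to_numpy()
                )
                score_frame.attrs[f"r_PC{axis + 1}"] = r
                geometry_rows.append(
                    {
                        "pair": ("shape_score", f"PC{axis + 1}"),
                        "mode": "score_correlation",
                        "correlation_mean": r,
                        "correlation_p": p,
                    }
                )

        geometry = pd.DataFrame(geometry_rows)

        log = {
            "seed": config.seed,
            "n_input": len(dataset.specimen_ids) + len(report.outlier_ids),
            "n_retained": len(dataset.specimen_ids),
            "n_modelled": int(len(table_all)),
            "outliers": report.outlier_ids,
            "n_pcs": m,
            "python": platform.python_version(),
            "numpy": np.__version__,
        }
        result = PipelineResult(
            screening_report=report.to_dict(),
            pca_diagnostic=diagnostic,
            model_table=table_all,
            summaries=summaries,
            comparisons=comparisons,
            geometry=geometry,
            shape_scores=score_frame,
            log=log,
        )
        if config.outdir:
            _write_report(result, Path(config.outdir))
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_report(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "screening.json").write_text(
        json.dumps(result.screening_report, indent=1, sort_keys=True)
    )
    (outdir / "pca.json").write_text(
        json.dumps(result.pca_diagnostic, indent=1, sort_keys=True)
    )
    result.model_table.to_csv(outdir / "model_table.csv", index=False)
    tables = []
    for label, summary in result.summaries.items():
        t = summary.table.copy()
        t.insert(0, "model", label)
        t["waic"] = summary.waic
        t["bayes_r2"] = summary.bayes_r2
        tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(
        outdir / "model_summaries.csv", index=False
    )
    comp = []
    for label, df in result.comparisons.items():
        d = df.copy()
        d.insert(0, "comparison", label)
        comp.append(d)
    pd.concat(comp, ignore_index=True).to_csv(
        outdir / "waic_comparison.csv", index=False
    )
    result.geometry.to_csv(outdir / "effect_geometry.csv", index=False)
    result.shape_scores.to_csv(outdir / "shape_scores.csv", index=False)
    (outdir / "run.json").write_text(json.dumps(result.log, indent=1, sort_keys=True))
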