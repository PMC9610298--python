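"""End-to-end activity/PES workflow.

The pipeline links two reduced spaces: the first principal component of the
compounds' (Ki_BChE, Ki_AChE) inhibition matrix — a one-dimensional activity
score — is regressed, per compound series, on the first few principal
components of the compound x energy-fingerprint matrix, using the exhaustive
polynomial model search.  The activity PCA is computed once on the full
table and then subset per series, so all series share one activity scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pca
from .model_search import SearchConfig, SearchResult, exhaustive_search

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "build_activity_response",
    "build_pes_predictors",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: Default split of compound series into the two modelled families.
DEFAULT_SERIES_GROUPS = {
    "CD-derivatives": ("CD", "DHCD"),
    "CN-derivatives": ("CN", "DHCN"),
}


class PipelineError(RuntimeError):
    """Raised with a stage-named message when a pipeline stage fails."""


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs and settings for one pipeline run.

    ``ki_table`` needs columns compound,series,Ki_BChE_uM,Ki_AChE_uM;
    ``fingerprints`` is a compound x fingerprint-length matrix indexed by the
    same compound ids.  ``n_pes_components`` (default 3) sets how many PES
    principal components feed the regression.
    """

    ki_table: pd.DataFrame
    fingerprints: pd.DataFrame
    n_pes_components: int = 3
    series_groups: dict = field(default_factory=lambda: dict(DEFAULT_SERIES_GROUPS))
    search: SearchConfig = field(default_factory=lambda: SearchConfig(max_order=2))
    log_transform_ki: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pes_components < 1:
            raise ValueError("n_pes_components must be >= 1")


def build_activity_response(ki_table: pd.DataFrame, log_transform: bool = False):
    """PC1 scores of the mean-centered (Ki_BChE, Ki_AChE) matrix.

    Returns (scores Series indexed by compound, PCAResult).  The scores are
    mean-zero by construction and serve as the regression response.
    """
    if len(ki_table) < 3:
        raise PipelineError("activity stage: need at least 3 compounds")
    X = ki_table[["Ki_BChE_uM", "Ki_AChE_uM"]].to_numpy(dtype=float)
    if log_transform:
        X = np.log10(X)
    result = pca.nipals_pca(X, k=1)
    scores = pd.Series(result.scores[:, 0], index=ki_table["compound"].to_numpy())
    return scores, result


def build_pes_predictors(fingerprints: pd.DataFrame, k: int):
    """First k PCA score columns of the compound x fingerprint matrix."""
    n = len(fingerprints)
    if n < k + 1:
        raise PipelineError(
            f"PES stage: need at least k+1={k + 1} compounds, got {n}"
        )
    values = fingerprints.to_numpy(dtype=float)
    if np.allclose(values, values[0]):  # identical fingerprints: zero scores
        zeros = pd.DataFrame(
            np.zeros((n, k)), index=fingerprints.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        return zeros, None
    result = pca.nipals_pca(values, k=k)
    scores = pd.DataFrame(
        result.scores, index=fingerprints.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run activity PCA, PES PCA and the per-series model search.

    Returns a self-describing report dict (JSON-serialisable apart from the
    embedded per-series fitted/observed tables, which are plain lists).
    Deterministic given the inputs and seed.
    """
    try:
        response, activity_pca = build_activity_response(
            config.ki_table, config.log_transform_ki
        )
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError(f"activity stage failed: {exc}") from exc

    try:
        predictors, pes_pca = build_pes_predictors(
            config.fingerprints, config.n_pes_components
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"PES stage failed: {exc}") from exc

    missing = set(response.index) - set(predictors.index)
    if missing:
        raise PipelineError(
            f"join stage failed: compounds without fingerprints: {sorted(missing)[:5]}"
        )

    report: dict = {
        "config": {
            "n_pes_components": config.n_pes_components,
            "series_groups": {k: list(v) for k, v in config.series_groups.items()},
            "search": {
                "max_order": config.search.max_order,
                "max_terms_per_model": config.search.max_terms_per_model,
            },
            "log_transform_ki": config.log_transform_ki,
            "seed": config.seed,
        },
        "activity_pca": {
            "explained_fraction": activity_pca.explained_fraction.tolist(),
            "eigenvalues": activity_pca.eigenvalues.tolist(),
        },
        "pes_pca": {
            "explained_fraction": (
                pes_pca.explained_fraction.tolist() if pes_pca else None
            ),
        },
        "series": {},
    }

    for group_name, series_values in config.series_groups.items():
        mask = config.ki_table["series"].isin(series_values).to_numpy()
        compounds = config.ki_table.loc[mask, "compound"].to_numpy()
        if len(compounds) < 3:
            logger.warning("series %s has %d compounds; skipped", group_name, len(compounds))
            continue
        y = response.loc[compounds].to_numpy()
        X = predictors.loc[compounds].to_numpy()
        logger.info("series %s: searching models for %d compounds", group_name, len(compounds))
        try:
            result = exhaustive_search(X, y, config.search)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"search stage failed for {group_name}: {exc}") from exc
        assert isinstance(result, SearchResult)
        best = result.best
        from .model_search import predict as _predict

        fitted = _predict(best, result.basis, X)[:, 0]
        pred_r2 = float(np.mean(best.predicted_r2))
        if pred_r2 < 0.5:
            logger.warning(
                "series %s: best model predicted R^2 = %.3f — no usable "
                "activity/PES link", group_name, pred_r2,
            )
        report["series"][group_name] = {
            "n_compounds": int(len(compounds)),
            "best_model": best.summary(result.basis),
            "predicted_r2": pred_r2,
            "low_signal": pred_r2 < 0.5,
            "fitted_vs_observed": [
                {"compound": str(c), "fitted": float(f), "observed": float(o)}
                for c, f, o in zip(compounds, fitted, y)
            ],
        }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
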