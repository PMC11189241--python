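"""Aggregate per-record SHAP attributions into cohort-level importance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treeshap import ShapMatrix, tree_shap


@dataclass
class ImportanceSummary:
    """participant x feature mean |SHAP| matrix plus the global ranking."""

    matrix: pd.DataFrame          # index: participant, columns: features
    ranking: list[str]            # features by descending cross-participant mean
    top: list[str]                # the top-k slice of ranking
    signed: pd.DataFrame          # per participant-feature signed summaries


def shap_for_evaluation(result, check_additivity: bool = True) -> dict[str, tuple[ShapMatrix, pd.DataFrame]]:
    """Attributions for every personal model's test records.

    ``result`` must come from :func:`lonesense.model.evaluate_all` with
    ``keep_models=True``.
    """
    if not result.models:
        raise ValueError("evaluation was run without keep_models=True")
    out = {}
    for pid, (rf, X_test, _) in result.models.items():
        out[pid] = (tree_shap(rf, X_test, check_additivity=check_additivity), X_test)
    return out


def aggregate_importance(shap_by_participant: dict[str, tuple[ShapMatrix, pd.DataFrame]],
                         top_k: int = 20) -> ImportanceSummary:
    """Mean |SHAP| per (participant, feature); features ranked by the
    cross-participant mean; signed per-participant summaries retained."""
    rows = {}
    signed_rows = []
    for pid, (shap, X) in shap_by_participant.items():
        rows[pid] = pd.Series(shap.mean_abs(), index=shap.feature_names)
        vals = X.to_numpy(float)
        for j, feat in enumerate(shap.feature_names):
            sj = shap.values[:, j]
            xj = vals[:, j]
            if np.std(sj) > 1e-12 and np.std(xj) > 1e-12:
                corr = float(np.corrcoef(xj, sj)[0, 1])
            else:
                corr = np.nan
            signed_rows.append((pid, feat, float(sj.mean()), corr))
    matrix = pd.DataFrame(rows).T.sort_index()
    order = matrix.mean(axis=0).sort_values(ascending=False)
    ranking = list(order.index)
    signed = pd.DataFrame(signed_rows,
                          columns=["participant_id", "feature", "mean_shap",
                                   "value_shap_corr"])
    return ImportanceSummary(matrix, ranking, ranking[:top_k], signed)
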