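"""Report tables, the survivor-accuracy chart, and run manifests.

The writers mirror the layout of the study-style outputs: a univariate
coefficient table (estimate / SE / Wald p per variable), a nested-model
likelihood-ratio table, and per-model 2x2 per-class accuracy tables from
cross-validation, plus a grouped-bar chart of survivor accuracies.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort
from .cv import CvSummary
from .glm import (
    OBJECTIVE_SCORES,
    SUBJECTIVE_INDEXES,
    LadderReport,
    ModelSpec,
    fit_logistic,
    wald_test,
)


def univariate_wald_table(
    cohort: Cohort,
    variables: tuple[str, ...] = (*SUBJECTIVE_INDEXES, *OBJECTIVE_SCORES),
) -> pd.DataFrame:
    """Estimate, SE and Wald p-value of each single-predictor model."""
    rows = []
    for var in variables:
        fit = fit_logistic(cohort, ModelSpec((var,)))
        res = wald_test(fit, var)
        rows.append(
            {
                "variable": var,
                "estimate": fit.coef(var),
                "se": fit.se(var),
                "p": res.p_value,
                "converged": fit.converged,
                "separation_flag": fit.separation_flag,
            }
        )
    return pd.DataFrame(rows)


def nested_lrt_table(ladder: LadderReport) -> pd.DataFrame:
    """All likelihood-ratio comparisons performed by the selection ladder."""
    return ladder.lrt_table.copy()


def accuracy_table(summary: CvSummary) -> pd.DataFrame:
    """2x2 per-class accuracy table (percent) for one cross-validated model."""
    surv = summary.survivor_accuracy
    nonsurv = summary.nonsurvivor_accuracy
    return pd.DataFrame(
        {
            "model": [summary.model.name] * 2,
            "predicted": ["survivor", "nonsurvivor"],
            "real_survivors_pct": [100 * surv, 100 * (1 - surv)],
            "real_nonsurvivors_pct": [100 * (1 - nonsurv), 100 * nonsurv],
        }
    )


def accuracy_tables(summaries: list[CvSummary]) -> pd.DataFrame:
    return pd.concat([accuracy_table(s) for s in summaries], ignore_index=True)


def survivor_accuracy_chart(
    summaries_by_cohort: dict[str, list[CvSummary]], path: str | Path
) -> None:
    """Grouped-bar chart of mean survivor accuracy per model per cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cohorts = list(summaries_by_cohort)
    models = [s.model.name for s in next(iter(summaries_by_cohort.values()))]
    width = 0.8 / len(models)
    fig, ax = plt.subplots(figsize=(7, 4))
    for j, model in enumerate(models):
        xs = [i + j * width for i in range(len(cohorts))]
        ys = [100 * summaries_by_cohort[c][j].survivor_accuracy for c in cohorts]
        errs = [100 * summaries_by_cohort[c][j].survivor_accuracy_sd for c in cohorts]
        ax.bar(xs, ys, width=width, label=model, yerr=errs, capsize=3)
    ax.set_xticks([i + width * (len(models) - 1) / 2 for i in range(len(cohorts))])
    ax.set_xticklabels(cohorts)
    ax.set_ylabel("survivor accuracy (%)")
    ax.set_ylim(0, 100)
    ax.legend(title="model")
    ax.set_title("Survival prediction at the preset mortality sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every set of outputs."""

    seed: int | None
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    python: str = field(default_factory=platform.python_version)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[p.name] = _sha256(p)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = _sha256(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True, default=str) + "\n"
        )
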