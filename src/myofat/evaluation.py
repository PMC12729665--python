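"""Data splits, individuality statistics, accuracy metrics and error maps.

The evaluation protocol runs five train/test partitions of the 25x15
dataset: in three of them the test set is the 3 repeats with fixed indices
from every object, in two it is 3 randomly drawn repeats per object.
Accuracy is reported at the object level (one prediction per phantom,
signal-level estimates averaged) with Pearson R, the coefficient of
determination R^2, the sum of squared errors SSE and the standard error of
estimate SEE = sqrt(SSE/(n-2)).

The individuality index II = CV.o/CV.m (mean within-object coefficient of
variation over the whole-dataset coefficient of variation) and its
reciprocal RII quantify how well a criterion discriminates between objects:
low II / high RII means repeat-to-repeat scatter is small compared with the
between-object spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import CRITERION_COLUMNS

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "default_split_plans",
    "make_splits",
    "individuality",
    "individuality_from_cvs",
    "regression_metrics",
    "error_topology",
    "render_error_map",
    "compare_methods",
]


@dataclass(frozen=True)
class SplitPlan:
    """One train/test partition: 3 of the 15 repeats per object for testing."""

    mode: str                                   # "by_index" | "random"
    test_repeats: tuple[int, ...] = ()          # for by_index
    seed: int = 0                               # for random
    n_test: int = 3
    name: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("by_index", "random"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "by_index" and len(self.test_repeats) != self.n_test:
            raise ValueError("by_index plan needs exactly n_test repeat indices")


def default_split_plans(seed: int = 0) -> list[SplitPlan]:
    """Five partitions: three index-based, two random (seeded)."""
    base = (seed % 2 ** 30) * 2
    return [
        SplitPlan("by_index", (1, 2, 3), name="split1"),
        SplitPlan("by_index", (6, 7, 8), name="split2"),
        SplitPlan("by_index", (11, 12, 13), name="split3"),
        SplitPlan("random", seed=base + 1, name="split4"),
        SplitPlan("random", seed=base + 2, name="split5"),
    ]


def make_splits(records: pd.DataFrame, plans: list[SplitPlan]
                ) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Partition criterion records into (train, test) per plan.

    ``records`` needs ``phantom_id`` and ``repeat`` columns with the same
    repeat indices for every object.
    """
    out = []
    for plan in plans:
        if plan.mode == "by_index":
            mask = records["repeat"].isin(plan.test_repeats)
        else:
            rng = np.random.default_rng(plan.seed)
            repeats = np.sort(records["repeat"].unique())
            mask = pd.Series(False, index=records.index)
            for _, grp in records.groupby("phantom_id"):
                chosen = rng.choice(repeats, size=plan.n_test, replace=False)
                mask.loc[grp.index[grp["repeat"].isin(chosen)]] = True
        test = records[mask]
        train = records[~mask]
        n_obj = records["phantom_id"].nunique()
        if (test.groupby("phantom_id").size() != plan.n_test).any() \
                or test["phantom_id"].nunique() != n_obj:
            raise ValueError(f"{plan.name}: every object needs exactly "
                             f"{plan.n_test} test signals")
        out.append((train, test))
    return out


def individuality(records: pd.DataFrame,
                  criteria: list[str] | None = None) -> pd.DataFrame:
    """Per-criterion M, SD.m, CV.m, SD.o, CV.o, II and RII.

    Within-object statistics are computed per object and averaged; the
    whole-dataset statistics pool all records.
    """
    criteria = criteria or CRITERION_COLUMNS
    if records["phantom_id"].nunique() < 2:
        raise ValueError("need at least two objects")
    if (records.groupby("phantom_id").size() < 2).any():
        raise ValueError("need at least two records per object")
    rows = {}
    grouped = records.groupby("phantom_id")
    for crit in criteria:
        x = records[crit].to_numpy(dtype=float)
        m = x.mean()
        sd_m = x.std(ddof=1)
        if m == 0:
            raise ValueError(f"zero dataset mean for {crit}")
        cv_m = sd_m / m
        per_obj = grouped[crit].agg(["mean", "std"])
        sd_o = per_obj["std"].mean()
        cv_o = (per_obj["std"] / per_obj["mean"]).mean()
        if cv_m == 0:
            raise ValueError(f"zero dataset CV for {crit}")
        ii = cv_o / cv_m
        rows[crit] = {"M": m, "SD.m": sd_m, "CV.m": cv_m,
                      "SD.o": sd_o, "CV.o": cv_o,
                      "II": ii, "RII": np.inf if ii == 0 else 1.0 / ii}
    return pd.DataFrame(rows).T


def individuality_from_cvs(cv_o: float, cv_m: float) -> tuple[float, float]:
    """II and RII from already-known coefficients of variation."""
    if cv_m <= 0 or cv_o < 0:
        raise ValueError("CVs must be positive")
    ii = cv_o / cv_m
    return ii, (np.inf if ii == 0 else 1.0 / ii)


@dataclass
class MetricsReport:
    """Object-level accuracy metrics for one target variable."""

    target: str
    r: float
    r2: float
    sse: float
    see: float
    mae: float
    mae_sd: float
    n: int
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"target": self.target, "R": self.r, "R2": self.r2,
                "SSE": self.sse, "SEE": self.see, "MAE": self.mae,
                "MAE_SD": self.mae_sd, "n": self.n, **self.extras}


def regression_metrics(y_true, y_pred, target: str = "") -> MetricsReport:
    """Pearson R, R^2, SSE and SEE (df = n - 2) for object-level predictions."""
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.size != yp.size:
        raise ValueError("prediction/truth length mismatch")
    if yt.size < 3:
        raise ValueError("need at least three objects for SEE (df = n - 2)")
    err = yp - yt
    sse = float(np.sum(err ** 2))
    see = float(np.sqrt(sse / (yt.size - 2)))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else np.nan
    r = float(stats.pearsonr(yt, yp).statistic) if np.std(yp) > 0 else np.nan
    return MetricsReport(target=target, r=r, r2=r2, sse=sse, see=see,
                         mae=float(np.mean(np.abs(err))),
                         mae_sd=float(np.std(np.abs(err), ddof=1)),
                         n=yt.size)


def error_topology(truth: pd.DataFrame, predictions: pd.DataFrame,
                   target: str, levels=None) -> pd.DataFrame:
    """5x5 matrix of per-object absolute errors over the SAT-IMAT grid.

    Both frames need ``sat``/``imat`` truth columns; ``predictions``
    additionally a ``pred_<target>`` column.  Rows index SAT levels,
    columns IMAT levels.
    """
    merged = truth.merge(predictions, on=["sat", "imat"])
    if levels is None:
        levels = np.unique(truth["sat"])
    mat = pd.DataFrame(np.nan, index=levels, columns=levels)
    for _, row in merged.iterrows():
        mat.loc[row["sat"], row["imat"]] = abs(row[f"pred_{target}"]
                                               - row[target])
    mat.index.name = "sat"
    mat.columns.name = "imat"
    return mat


def render_error_map(error_map: pd.DataFrame, path, title: str = "") -> None:
    """Save an error-topology heatmap to ``path`` (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(error_map.to_numpy(), origin="lower", cmap="viridis")
    ax.set_xticks(range(len(error_map.columns)),
                  [f"{c:g}" for c in error_map.columns])
    ax.set_yticks(range(len(error_map.index)),
                  [f"{r:g}" for r in error_map.index])
    ax.set_xlabel("IMAT, %")
    ax.set_ylabel("SAT, %")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="|error|, %")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_methods(per_split_results: dict[str, dict[str, dict[str, MetricsReport]]]
                    ) -> pd.DataFrame:
    """Mean-error comparison table across splits, methods and targets.

    ``per_split_results[split][method][target]`` is a MetricsReport; the
    returned frame has one row per (split, method, target) plus an
    ``average`` row per method and target.
    """
    rows = []
    for split, by_method in per_split_results.items():
        for method, by_target in by_method.items():
            for target, rep in by_target.items():
                rows.append({"split": split, "method": method,
                             "target": target, **rep.as_dict()})
    table = pd.DataFrame(rows).drop(columns=["n"])
    means = (table.groupby(["method", "target"], as_index=False)
             .mean(numeric_only=True))
    means.insert(0, "split", "average")
    return pd.concat([table, means], ignore_index=True)
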