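"""Expression–phenotype association: Spearman screen, regression cascade, composite score."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def collagen_score(col1a1: float, col1a2: float, col3a1: float) -> float:
    """Equal-weights composite of the three collagen transcripts (each 1/3)."""
    vals = (col1a1, col1a2, col3a1)
    for name, v in zip(("col1a1", "col1a2", "col3a1"), vals):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return (col1a1 + col1a2 + col3a1) / 3.0


def spearman_assoc(
    tbl: pd.DataFrame, target: str, min_pairs: int = 5
) -> pd.DataFrame:
    """Pairwise-complete Spearman rho (two-tailed P) of each covariate vs target.

    Constant covariates get NaN rho with ``defined`` False rather than being
    dropped. Rows are ordered by covariate name.
    """
    if target not in tbl.columns:
        raise KeyError(f"target column {target!r} not in table")
    covars = [c for c in tbl.columns if c not in ("subject_id", target)]
    rows = []
    for name in sorted(covars):
        pair = tbl[[name, target]].dropna()
        n = len(pair)
        if n < min_pairs:
            raise ValueError(
                f"covariate {name!r} has only {n} non-missing pairs (< {min_pairs})"
            )
        x, y = pair[name].to_numpy(float), pair[target].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append(
                {"covariate": name, "rho": np.nan, "p_two_tailed": np.nan,
                 "n": n, "defined": False}
            )
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append(
            {"covariate": name, "rho": float(rho), "p_two_tailed": float(p),
             "n": n, "defined": True}
        )
    return pd.DataFrame(rows)


class CollinearityError(ValueError):
    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient design: collinear columns " + ", ".join(self.columns)
        )


def _check_full_rank(design: pd.DataFrame) -> None:
    """Greedy dependence check; raises naming the dependent column and its parents."""
    x = design.to_numpy(float)
    cols = list(design.columns)
    kept: list[int] = []
    for j in range(x.shape[1]):
        if not kept:
            if np.linalg.norm(x[:, j]) == 0:
                raise CollinearityError([cols[j]])
            kept.append(j)
            continue
        basis = x[:, kept]
        coef, *_ = np.linalg.lstsq(basis, x[:, j], rcond=None)
        resid = x[:, j] - basis @ coef
        scale = np.linalg.norm(x[:, j]) or 1.0
        if np.linalg.norm(resid) < 1e-8 * scale:
            involved = [cols[kept[i]] for i in np.flatnonzero(np.abs(coef) > 1e-8)]
            raise CollinearityError(involved + [cols[j]])
        kept.append(j)


@dataclass
class RegressionReport:
    univariable: pd.DataFrame = field(default_factory=pd.DataFrame)
    stage1_selected: list[str] = field(default_factory=list)
    multivariable: pd.DataFrame = field(default_factory=pd.DataFrame)
    retained: list[str] = field(default_factory=list)
    elimination_order: list[dict] = field(default_factory=list)
    alpha: float = 0.05


def _encode_covariates(tbl: pd.DataFrame, covars: list[str]) -> pd.DataFrame:
    """Numeric columns pass through; categoricals are one-hot with the first
    level (sorted) as reference."""
    pieces = []
    for name in covars:
        col = tbl[name]
        if pd.api.types.is_numeric_dtype(col):
            pieces.append(col.astype(float))
        else:
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                pieces.append((col == lev).astype(float).rename(f"{name}[{lev}]"))
    return pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=tbl.index)


def regression_cascade(
    tbl: pd.DataFrame, target: str, alpha: float = 0.05
) -> RegressionReport:
    """Univariable screen at ``alpha`` then backward elimination of the joint fit.

    Stage 1: OLS of target on each covariate alone (listwise-complete per
    fit); covariates with slope P < alpha advance. Stage 2: joint OLS on the
    survivors; repeatedly drop the covariate with the largest P >= alpha
    (ties broken by name) and refit, until every remaining covariate has
    P < alpha or none remain. The elimination order is recorded.
    """
    if target not in tbl.columns:
        raise KeyError(f"target column {target!r} not in table")
    covars = [c for c in tbl.columns if c not in ("subject_id", target)]
    design_all = _encode_covariates(tbl, covars)

    uni_rows = []
    for name in design_all.columns:
        sub = pd.concat([tbl[target], design_all[name]], axis=1).dropna()
        y = sub[target].to_numpy(float)
        x = sm.add_constant(sub[name].to_numpy(float))
        fit = sm.OLS(y, x).fit()
        uni_rows.append(
            {
                "covariate": name,
                "slope": float(fit.params[1]),
                "se": float(fit.bse[1]),
                "p": float(fit.pvalues[1]),
                "n": int(len(sub)),
            }
        )
    uni = pd.DataFrame(uni_rows)
    selected = sorted(uni.loc[uni["p"] < alpha, "covariate"])

    report = RegressionReport(univariable=uni, stage1_selected=list(selected), alpha=alpha)
    if not selected:
        return report

    current = list(selected)
    sub = pd.concat([tbl[target], design_all[selected]], axis=1).dropna()
    if len(sub) <= len(selected) + 1:
        raise ValueError(
            f"too few complete subjects ({len(sub)}) for {len(selected)} covariates"
        )
    _check_full_rank(sub[selected])

    y = sub[target].to_numpy(float)
    while current:
        x = sm.add_constant(sub[current].to_numpy(float))
        fit = sm.OLS(y, x).fit()
        pvals = pd.Series(fit.pvalues[1:], index=current)
        worst = pvals[pvals >= alpha]
        if worst.empty:
            report.multivariable = pd.DataFrame(
                {
                    "covariate": current,
                    "coef": fit.params[1:],
                    "se": fit.bse[1:],
                    "p": fit.pvalues[1:],
                }
            )
            report.retained = list(current)
            break
        # drop the largest P; ties broken by covariate name ascending
        max_p = worst.max()
        drop = sorted(worst.index[worst == max_p])[0]
        report.elimination_order.append({"dropped": str(drop), "p": float(worst[drop])})
        current.remove(drop)
    return report
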