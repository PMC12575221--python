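"""Multicollinearity screening of FPC scores at the variable level.

VIFs are computed per score column (column regressed on all other columns,
with intercept).  A variable is flagged when one of its score columns has
VIF above the threshold *and* that same column is strongly correlated
(|r| above the threshold) with a score column of a different variable.
Flagged variables are removed one at a time, worst max-VIF first, and the
screen is recomputed until nothing is flagged.  A removal set can also be
pinned explicitly to replicate a previously published screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VIF_CAP = np.inf
_R2_EPS = 1e-12


def variable_of(column: str) -> str:
    """Variable name owning a ``variable:component`` score column."""
    return column.rsplit(":", 1)[0]


def compute_vif(scores: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of every score column.

    VIF_c = 1 / (1 - R^2_c) with R^2_c from regressing column c on all other
    columns plus an intercept.  Perfectly collinear columns get ``inf``.
    """
    if scores.shape[1] < 2:
        raise ValueError("VIF requires at least 2 columns")
    if scores.shape[0] <= scores.shape[1]:
        raise ValueError(
            f"VIF requires more rows ({scores.shape[0]}) than columns ({scores.shape[1]})"
        )
    X = scores.to_numpy(dtype=float)
    n = X.shape[0]
    out = {}
    for i, col in enumerate(scores.columns):
        y = X[:, i]
        others = np.delete(X, i, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst <= 0.0:
            out[col] = 1.0  # constant column: no variance to inflate
            continue
        frac = float(resid @ resid) / sst  # 1 - R^2
        out[col] = VIF_CAP if frac < _R2_EPS else 1.0 / frac
    return pd.Series(out, name="vif")


@dataclass
class ScreenReport:
    """Outcome of the iterative VIF / correlation screen."""

    vif: pd.Series                       # final per-column VIFs
    pair_max_corr: pd.DataFrame          # per variable pair, max |r| across score columns
    removed_variables: list[str]
    retained_variables: list[str]
    max_vif_after: float
    removal_log: list[str] = field(default_factory=list)

    def log_lines(self) -> list[str]:
        lines = list(self.removal_log)
        lines.append(
            f"screen done: removed {self.removed_variables or 'nothing'}, "
            f"max VIF after = {self.max_vif_after:.3f}"
        )
        return lines


def _pair_max_corr(scores: pd.DataFrame) -> pd.DataFrame:
    corr = scores.corr().abs()
    variables = sorted({variable_of(c) for c in scores.columns})
    out = pd.DataFrame(0.0, index=variables, columns=variables)
    col_var = np.array([variable_of(c) for c in scores.columns])
    for a in variables:
        for b in variables:
            if a >= b:
                continue
            block = corr.loc[col_var == a, col_var == b]
            m = float(block.to_numpy().max()) if block.size else 0.0
            out.loc[a, b] = out.loc[b, a] = m
    return out


def _flagged(
    scores: pd.DataFrame, vif_threshold: float, corr_threshold: float, conjunctive: bool
) -> tuple[pd.Series, dict[str, float]]:
    vif = compute_vif(scores)
    corr = scores.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    col_var = np.array([variable_of(c) for c in scores.columns])
    cross = corr * (col_var[None, :] != col_var[:, None])
    max_cross = cross.max(axis=1)
    flagged: dict[str, float] = {}
    for i, col in enumerate(scores.columns):
        high_vif = vif[col] > vif_threshold
        high_corr = max_cross[i] > corr_threshold
        hit = (high_vif and high_corr) if conjunctive else (high_vif or high_corr)
        if hit:
            var = variable_of(col)
            flagged[var] = max(flagged.get(var, -np.inf), float(vif[col]))
    return vif, flagged


def screen_variables(
    scores: pd.DataFrame,
    vif_threshold: float = 10.0,
    corr_threshold: float = 0.7,
    conjunctive: bool = True,
    pinned_removal: list[str] | None = None,
) -> tuple[list[str], ScreenReport]:
    """Iteratively drop whole variables whose scores are collinear.

    Returns the retained variable list and a :class:`ScreenReport`.  With
    ``pinned_removal`` the given variables are removed unconditionally and no
    iteration happens (replication mode).
    """
    if not vif_threshold > 1.0:
        raise ValueError(f"vif_threshold must be > 1, got {vif_threshold}")
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError(f"corr_threshold must be in (0, 1), got {corr_threshold}")
    variables = sorted({variable_of(c) for c in scores.columns})
    removed: list[str] = []
    log: list[str] = []
    current = scores

    if pinned_removal is not None:
        unknown = set(pinned_removal) - set(variables)
        if unknown:
            raise ValueError(f"pinned variables not in score set: {sorted(unknown)}")
        removed = [v for v in variables if v in set(pinned_removal)]
        current = scores[[c for c in scores.columns if variable_of(c) not in set(removed)]]
        log.append(f"pinned removal of {removed}")
    else:
        while True:
            remaining_vars = sorted({variable_of(c) for c in current.columns})
            if len(remaining_vars) <= 1:
                log.append("stopping: removal would empty the predictor set")
                break
            _, flagged = _flagged(current, vif_threshold, corr_threshold, conjunctive)
            if not flagged:
                break
            # worst max-VIF first; alphabetical tie-break for determinism
            victim = max(sorted(flagged), key=lambda v: flagged[v])
            removed.append(victim)
            log.append(f"removed {victim!r} (max VIF {flagged[victim]:.3f})")
            current = current[[c for c in current.columns if variable_of(c) != victim]]

    retained = [v for v in variables if v not in set(removed)]
    final_vif = compute_vif(current) if current.shape[1] >= 2 else pd.Series(
        {c: 1.0 for c in current.columns}, name="vif"
    )
    report = ScreenReport(
        vif=final_vif,
        pair_max_corr=_pair_max_corr(current),
        removed_variables=removed,
        retained_variables=retained,
        max_vif_after=float(final_vif.max()) if len(final_vif) else 1.0,
        removal_log=log,
    )
    return retained, report
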