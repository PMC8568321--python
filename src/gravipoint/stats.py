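"""Mixed-model analysis of the 3 x 2 factorial design with planned contrasts.

For each movement direction separately (upward and downward movements are
never compared directly), per-target (or per-muscle) means of retained
movements are modelled with a linear mixed model: fixed effects are the full
gravity x compensation x target (kinematics, 3 x 2 x 7) or gravity x
compensation x muscle (EMG, 3 x 2 x 4) factorial, the random effect is a
per-participant intercept, estimated by REML.  Wald F statistics are
reported for the main effects and the gravity x compensation interaction
with containment-style denominator degrees of freedom.

Six planned comparisons of condition cell means (averaged over targets or
muscles) follow the fit: 1g-0g and 1g-2g (effect of gravity), 0g-0gC and
2g-2gC (benefit of compensation), 1g-0gC and 1g-2gC (restoration to
normogravity).  Each is a z test on the contrast estimate with Bonferroni
correction over the family of six; significance at 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import ValidationError

#: planned comparisons: label, (gravity, compensation) of each side; the
#: statistic is mean(first) - mean(second)
PLANNED_COMPARISONS = (
    ("1g-0g", ("normo", False), ("micro", False)),
    ("0g-0gC", ("micro", False), ("micro", True)),
    ("1g-0gC", ("normo", False), ("micro", True)),
    ("1g-2g", ("normo", False), ("hyper", False)),
    ("2g-2gC", ("hyper", False), ("hyper", True)),
    ("1g-2gC", ("normo", False), ("hyper", True)),
)

_CELL_KEYS = ["participant_id", "direction", "gravity_condition", "compensation"]


def aggregate(
    features: pd.DataFrame,
    response_cols: list[str] | None = None,
    unit_col: str = "target_distance_cm",
) -> pd.DataFrame:
    """Per-target (or per-muscle) means of retained movements.

    One row per participant x direction x gravity x compensation x unit;
    cells with no retained movements are simply absent (the mixed model
    tolerates the resulting imbalance).
    """
    if response_cols is None:
        response_cols = [
            c for c in ("duration_s", "signed_deviation_mm", "curvature_mm",
                        "rtpv", "peak_speed_mm_s", "iemg_mv_s", "iemg_normalized")
            if c in features.columns
        ]
    df = features
    if "retained" in df.columns:
        df = df[df["retained"].astype(bool)]
    keys = _CELL_KEYS + [unit_col]
    return df.groupby(keys, as_index=False, observed=True)[response_cols].mean()


@dataclass
class LmmFit:
    """A fitted per-direction mixed model plus everything contrasts need."""

    response: str
    direction: str
    unit_col: str
    effects: pd.DataFrame            # term, F, df_num, df_den, p
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    design_info: object
    unit_levels: list
    observed_cells: frozenset = frozenset()
    singular: bool = False
    fallback_ols: bool = False


def fit_lmm(
    cells: pd.DataFrame,
    response: str,
    unit_col: str = "target_distance_cm",
    direction: str | None = None,
) -> LmmFit:
    """REML linear mixed model for one movement direction.

    ``cells`` is the output of :func:`aggregate`.  Raises
    :class:`ValidationError` with fewer than 2 participants; a singular
    random-effects fit is flagged and refit as a fixed-effects (OLS) model.
    """
    df = cells.copy()
    if direction is not None:
        df = df[df["direction"] == direction]
    elif df["direction"].nunique() > 1:
        raise ValidationError("fit one direction at a time")
    else:
        direction = str(df["direction"].iloc[0])
    df = df.dropna(subset=[response])
    if df["participant_id"].nunique() < 2:
        raise ValidationError("mixed model needs at least 2 participants")
    df = df.assign(
        compensation=df["compensation"].astype(bool),
        _unit=df[unit_col].astype(str),
    )
    formula = f"{response} ~ C(gravity_condition) * C(compensation) * C(_unit)"
    singular = fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        try:
            res = model.fit(reml=True, method="lbfgs")
            singular = bool(np.any(np.diag(res.cov_re) < 1e-10))
            k = len(res.fe_params)
            fe = res.fe_params
            cov = pd.DataFrame(
                np.asarray(res.cov_params())[:k, :k], index=fe.index, columns=fe.index
            )
            n_re = df["participant_id"].nunique() - 1
        except Exception:
            fallback = True
            res = smf.ols(formula, df).fit()
            fe = res.params
            cov = res.cov_params()
            n_re = 0
            warnings.warn("mixed model failed; fell back to fixed effects")
        design_info = res.model.data.design_info

    n_obs = len(df)
    rank = len(fe)
    df_den = max(n_obs - rank - n_re, 1)
    rows = []
    slices = design_info.term_name_slices
    wanted = [
        "C(gravity_condition)",
        "C(compensation)",
        "C(_unit)",
        "C(gravity_condition):C(compensation)",
    ]
    fe_vec = fe.to_numpy()
    cov_mat = cov.to_numpy()
    for term in wanted:
        sl = slices.get(term)
        if sl is None:
            continue
        idx = np.arange(rank)[sl]
        L = np.zeros((len(idx), rank))
        L[np.arange(len(idx)), idx] = 1.0
        est = L @ fe_vec
        V = L @ cov_mat @ L.T
        chi2 = float(est @ np.linalg.solve(V, est))
        q = len(idx)
        F = chi2 / q
        p = float(sps.f.sf(F, q, df_den))
        label = term.replace("C(_unit)", f"C({unit_col})")
        rows.append({"term": label, "F": F, "df_num": q, "df_den": df_den, "p": p})
    effects = pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p"])
    return LmmFit(
        response=response,
        direction=direction,
        unit_col=unit_col,
        effects=effects,
        fe_params=fe,
        fe_cov=cov,
        design_info=design_info,
        unit_levels=sorted(df["_unit"].unique()),
        observed_cells=frozenset(
            zip(df["gravity_condition"], df["compensation"].astype(bool))
        ),
        singular=singular,
        fallback_ols=fallback,
    )


def _cell_design_row(fit: LmmFit, gravity: str, compensation: bool) -> np.ndarray | None:
    """Mean design-matrix row for one (gravity, compensation) cell over units."""
    new = pd.DataFrame(
        {
            "gravity_condition": gravity,
            "compensation": compensation,
            "_unit": fit.unit_levels,
        }
    )
    try:
        (mat,) = patsy.build_design_matrices([fit.design_info], new)
    except patsy.PatsyError:
        return None
    return np.asarray(mat).mean(axis=0)


def planned_contrasts(fit: LmmFit, family_size: int = 6, alpha: float = 0.05) -> pd.DataFrame:
    """The six planned comparisons with Bonferroni-adjusted p-values.

    An inestimable contrast (empty cell in the fit) is reported with NaN
    statistics rather than dropped.
    """
    rows = []
    fe = fit.fe_params.to_numpy()
    cov = fit.fe_cov.to_numpy()
    for label, (g1, c1), (g2, c2) in PLANNED_COMPARISONS:
        estimable = {(g1, c1), (g2, c2)} <= fit.observed_cells
        r1 = _cell_design_row(fit, g1, c1) if estimable else None
        r2 = _cell_design_row(fit, g2, c2) if estimable else None
        if r1 is None or r2 is None:
            rows.append(
                {"comparison": label, "estimate": np.nan, "z": np.nan,
                 "p_raw": np.nan, "p_adjusted": np.nan, "significant": False}
            )
            continue
        L = r1 - r2
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p * family_size)
        rows.append(
            {"comparison": label, "estimate": est, "z": z, "p_raw": p,
             "p_adjusted": p_adj, "significant": p_adj < alpha}
        )
    return pd.DataFrame(rows)


def bonferroni(p_raw: float, family_size: int = 6) -> float:
    """Bonferroni adjustment: min(1, p * family size)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValidationError("p_raw must lie in [0, 1]")
    return min(1.0, p_raw * family_size)


def analyze(
    features: pd.DataFrame,
    response: str,
    unit_col: str = "target_distance_cm",
    family_size: int = 6,
) -> pd.DataFrame:
    """Fit both directions and return the stacked contrast table."""
    cells = aggregate(features, [response], unit_col)
    out = []
    for direction in sorted(cells["direction"].unique()):
        fit = fit_lmm(cells, response, unit_col, direction)
        con = planned_contrasts(fit, family_size)
        con.insert(0, "direction", direction)
        con.insert(0, "response", response)
        out.append(con)
    return pd.concat(out, ignore_index=True)
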