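"""Layer-stratified group statistics on slice x layer average units.

The unit of analysis is not the single cell but the *layer average*: for
each slice, parameters of all accepted cells in a (residence layer,
stimulation layer) stratum with at least eight responsive cells are
averaged, and that average is one unit.  This avoids pseudo-replication
across the many cells of one slice.

The testing logic mirrors a fixed branching design:

* Shapiro–Wilk normality screen per parameter; distance-normalized
  latency and decay-time are analyzed on the log scale (log-normal),
  the others on the identity scale.
* Levene's test (center = mean) compares between-group variance.
* If variances are homogeneous -> factorial ANOVA with post hoc Tukey HSD.
* If Levene rejects (heteroscedastic groups, as for amplitude) -> a
  parametric-bootstrap ANOVA: group means are fit under the null of the
  tested effect, B datasets are simulated from normals with
  *group-specific* variances, and the p value is the bootstrap tail
  probability of the observed F.
* Sex effects: Welch t tests (Satterthwaite df).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "PARAMETER_TRANSFORMS",
    "layer_averages",
    "normality_screen",
    "variance_screen",
    "welch_t",
    "factorial_anova_tukey",
    "bootstrap_anova",
    "run_group_stats",
    "simulate_layer_units",
]

#: analysis scale per parameter (identity unless stated log-normal)
PARAMETER_TRANSFORMS = {
    "amplitude_pct": "identity",
    "half_width_ms": "identity",
    "rise_time_ms": "identity",
    "dn_latency_ms_per_um": "log",
    "decay_time_ms": "log",
}

PARAMETERS = list(PARAMETER_TRANSFORMS)

DESIGN_FACTORS = ["genotype", "residence_layer", "stimulation_layer"]


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple[float, ...] | None
    p_value: float
    transform: str = "identity"
    groups: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return np.asarray(values, dtype=float)
    if transform == "log":
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(values)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# units

def layer_averages(
    cell_table: pd.DataFrame,
    min_n: int = 8,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Per-slice, per-(residence, stimulation) layer parameter means.

    Strata with fewer than ``min_n`` cells are dropped.  Only L2/3 and L4
    cells (``in_analysis``) contribute.
    """
    parameters = parameters or PARAMETERS
    df = cell_table[cell_table["in_analysis"]].copy()
    keys = ["slice_id", "residence_layer", "stimulation_layer"]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        if len(grp) < min_n:
            continue
        row = dict(zip(keys, key))
        row["genotype"] = grp["genotype"].iloc[0]
        row["sex"] = grp["sex"].iloc[0]
        row["n_cells"] = len(grp)
        for p in parameters:
            row[p] = float(grp[p].mean())
        rows.append(row)
    cols = ["slice_id", "genotype", "sex", "residence_layer", "stimulation_layer", "n_cells"] + parameters
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# screens

def normality_screen(
    units: pd.DataFrame, parameter: str, transform: str | None = None
) -> StatResult:
    """Shapiro–Wilk on the parameter's analysis scale."""
    transform = transform or PARAMETER_TRANSFORMS.get(parameter, "identity")
    x = _apply_transform(units[parameter].to_numpy(), transform)
    if x.size < 3:
        raise ValueError("need at least 3 units for a normality test")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return StatResult("shapiro_wilk", float(w), None, float(p), transform, (parameter,))


def _group_values(
    units: pd.DataFrame, parameter: str, by: list[str], transform: str
) -> tuple[list[np.ndarray], list[str]]:
    groups, labels = [], []
    for key, grp in units.groupby(by, sort=True):
        vals = _apply_transform(grp[parameter].to_numpy(), transform)
        groups.append(vals)
        labels.append(key if isinstance(key, str) else ":".join(map(str, key)))
    return groups, labels


def variance_screen(
    units: pd.DataFrame,
    parameter: str,
    by: list[str] | str = DESIGN_FACTORS,
    transform: str | None = None,
) -> StatResult:
    """Levene's test (center = mean) for between-group variance."""
    by = [by] if isinstance(by, str) else list(by)
    transform = transform or PARAMETER_TRANSFORMS.get(parameter, "identity")
    groups, labels = _group_values(units, parameter, by, transform)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Levene's test needs >= 2 groups with >= 2 units each")
    f, p = sps.levene(*groups, center="mean")
    n = sum(len(g) for g in groups)
    return StatResult(
        "levene", float(f), (len(groups) - 1, n - len(groups)), float(p), transform, tuple(labels)
    )


def welch_t(
    units: pd.DataFrame,
    parameter: str,
    grouping: str = "sex",
    transform: str | None = None,
) -> StatResult:
    """Welch two-sample t test with Satterthwaite degrees of freedom."""
    transform = transform or PARAMETER_TRANSFORMS.get(parameter, "identity")
    groups, labels = _group_values(units, parameter, [grouping], transform)
    if len(groups) != 2:
        raise ValueError(f"grouping {grouping!r} must define exactly 2 groups")
    a, b = groups
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 units")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult("welch_t", float(t), (float(df),), float(p), transform, tuple(labels))


# ---------------------------------------------------------------------------
# classical factorial ANOVA + Tukey

def factorial_anova_tukey(
    units: pd.DataFrame,
    parameter: str,
    factors: list[str] = DESIGN_FACTORS,
    include_interactions: bool = True,
    transform: str | None = None,
) -> dict:
    """Factorial ANOVA (type II) plus Tukey HSD over the crossed cells.

    Returns ``{"anova": {term: StatResult}, "tukey": DataFrame}``.
    Raises if any cell of the crossed design is empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    transform = transform or PARAMETER_TRANSFORMS.get(parameter, "identity")
    data = units.copy()
    data["_y"] = _apply_transform(data[parameter].to_numpy(), transform)

    from itertools import product

    observed = set(map(tuple, data[factors].drop_duplicates().itertuples(index=False)))
    missing = [
        ix for ix in product(*[sorted(data[f].unique()) for f in factors]) if ix not in observed
    ]
    if missing:
        raise ValueError(f"empty design cells: {missing}")

    op = " * " if include_interactions else " + "
    formula = "_y ~ " + op.join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    results: dict[str, StatResult] = {}
    df_resid = float(table.loc["Residual", "df"])
    for term in table.index:
        if term == "Residual":
            continue
        clean = term.replace("C(", "").replace(")", "")
        results[clean] = StatResult(
            "anova_F",
            float(table.loc[term, "F"]),
            (float(table.loc[term, "df"]), df_resid),
            float(table.loc[term, "PR(>F)"]),
            transform,
            (clean,),
        )

    cell_labels = data[factors].astype(str).agg(":".join, axis=1)
    tukey = pairwise_tukeyhsd(endog=data["_y"].to_numpy(), groups=cell_labels.to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    return {"anova": results, "tukey": tukey_df, "transform": transform}


# ---------------------------------------------------------------------------
# parametric bootstrap ANOVA (heteroscedastic groups)

def _term_columns(data: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    """Treatment-coded dummy columns for a main effect or interaction term."""
    mats = []
    for f in term:
        d = pd.get_dummies(data[f].astype(str), drop_first=True).to_numpy(dtype=float)
        mats.append(d)
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ni,nj->nij", out, m).reshape(len(data), -1)
    return out


def _model_terms(factors: list[str], include_interactions: bool) -> list[tuple[str, ...]]:
    terms: list[tuple[str, ...]] = [(f,) for f in factors]
    if include_interactions:
        for r in range(2, len(factors) + 1):
            terms.extend(combinations(factors, r))
    return terms


def _design_matrix(data: pd.DataFrame, terms: list[tuple[str, ...]]) -> np.ndarray:
    cols = [np.ones((len(data), 1))]
    cols += [_term_columns(data, t) for t in terms]
    return np.hstack(cols)


def _rss_projector(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Return (hat matrix, rank) for least squares onto columns of x."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps))
    u = u[:, :rank]
    return u @ u.T, rank


def bootstrap_anova(
    units: pd.DataFrame,
    parameter: str = "amplitude_pct",
    factors: list[str] = DESIGN_FACTORS,
    effect: str | tuple[str, ...] = "genotype",
    B: int = 10_000,
    *,
    seed: int,
    include_interactions: bool = True,
    transform: str | None = None,
) -> StatResult:
    """Parametric-bootstrap F test of one effect with heteroscedastic groups.

    The observed F compares the full factorial model against the model
    without the tested term.  Under the null, unit means are taken from
    the restricted fit and per-design-cell variances from the data; B
    datasets are simulated from those heteroscedastic normals and the p
    value is (1 + #{F_b >= F_obs}) / (B + 1).  Fully seed-controlled.
    """
    if isinstance(effect, str):
        effect = (effect,)
    effect = tuple(effect)
    if B < 100:
        warnings.warn(f"B={B} is small for a bootstrap p value", stacklevel=2)

    transform = transform or PARAMETER_TRANSFORMS.get(parameter, "identity")
    data = units.reset_index(drop=True)
    y = _apply_transform(data[parameter].to_numpy(), transform)
    n = y.size

    terms = _model_terms(list(factors), include_interactions)
    if effect not in terms:
        raise ValueError(f"effect {effect} not a term of the model {terms}")
    x_full = _design_matrix(data, terms)
    x_rest = _design_matrix(data, [t for t in terms if t != effect])

    h_full, rank_full = _rss_projector(x_full)
    h_rest, rank_rest = _rss_projector(x_rest)
    df1 = rank_full - rank_rest
    df2 = n - rank_full
    if df1 < 1 or df2 < 1:
        raise ValueError("degenerate design: no degrees of freedom for the test")

    def f_stat(Y: np.ndarray) -> np.ndarray:
        rss_f = np.sum((Y - h_full @ Y) ** 2, axis=0)
        rss_r = np.sum((Y - h_rest @ Y) ** 2, axis=0)
        return ((rss_r - rss_f) / df1) / (rss_f / df2)

    f_obs = float(f_stat(y[:, None])[0])

    # null means from the restricted fit; variances per design cell
    mu0 = h_rest @ y
    cell_labels = data[list(factors)].astype(str).agg(":".join, axis=1).to_numpy()
    sigma = np.empty(n)
    for lab in np.unique(cell_labels):
        idx = np.nonzero(cell_labels == lab)[0]
        if idx.size < 2:
            raise ValueError("each design cell needs >= 2 units for a variance estimate")
        sigma[idx] = y[idx].std(ddof=1)

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(B, int(5e7 // max(n * n, 1))))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        sim = mu0[:, None] + sigma[:, None] * rng.standard_normal((n, b))
        exceed += int(np.sum(f_stat(sim) >= f_obs))
        done += b
    p = (1 + exceed) / (B + 1)
    return StatResult(
        "bootstrap_anova_F",
        f_obs,
        (float(df1), float(df2)),
        float(p),
        transform,
        (":".join(effect),),
        extras={"B": B, "seed": seed},
    )


# ---------------------------------------------------------------------------
# orchestration

def run_group_stats(
    units: pd.DataFrame,
    parameters: list[str] | None = None,
    alpha: float = 0.05,
    B: int = 10_000,
    seed: int = 0,
) -> dict:
    """Full branching analysis over all parameters.

    Per parameter: normality screen (fixes the scale), Levene across the
    genotype x residence x stimulation cells, then classical factorial
    ANOVA + Tukey (homoscedastic) or parametric-bootstrap ANOVA per term
    (heteroscedastic).  Sex is screened with Levene and tested with Welch.
    """
    parameters = parameters or PARAMETERS
    report: dict = {}
    for i, param in enumerate(parameters):
        entry: dict = {}
        transform = PARAMETER_TRANSFORMS.get(param, "identity")
        entry["normality"] = normality_screen(units, param, transform)
        entry["levene_sex"] = variance_screen(units, param, "sex", transform)
        entry["sex_effect"] = welch_t(units, param, "sex", transform)
        lev = variance_screen(units, param, DESIGN_FACTORS, transform)
        entry["levene_design"] = lev
        if lev.p_value < alpha:
            entry["branch"] = "bootstrap_anova"
            terms = _model_terms(DESIGN_FACTORS, include_interactions=True)
            entry["effects"] = {
                ":".join(t): bootstrap_anova(
                    units, param, DESIGN_FACTORS, t, B=B, seed=seed + 1000 * i + hash_term(t)
                )
                for t in terms
            }
        else:
            entry["branch"] = "anova_tukey"
            entry["effects"] = factorial_anova_tukey(units, param, transform=transform)
        report[param] = entry
    return report


def hash_term(term: tuple[str, ...]) -> int:
    # stable small offset per model term (not Python's salted hash)
    return sum((i + 1) * (ord(t[0]) + len(t)) for i, t in enumerate(term)) % 997


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a run_group_stats report into a tidy DataFrame."""
    rows = []
    for param, entry in report.items():
        for key, val in entry.items():
            if isinstance(val, StatResult):
                rows.append(
                    {
                        "parameter": param,
                        "test": key,
                        "name": val.name,
                        "statistic": val.statistic,
                        "df": str(val.df),
                        "p_value": val.p_value,
                        "transform": val.transform,
                        "groups": ":".join(val.groups),
                    }
                )
            elif key == "effects" and isinstance(val, dict) and "anova" in val:
                for term, res in val["anova"].items():
                    rows.append(
                        {
                            "parameter": param,
                            "test": f"anova[{term}]",
                            "name": res.name,
                            "statistic": res.statistic,
                            "df": str(res.df),
                            "p_value": res.p_value,
                            "transform": res.transform,
                            "groups": term,
                        }
                    )
            elif key == "effects" and isinstance(val, dict):
                for term, res in val.items():
                    if isinstance(res, StatResult):
                        rows.append(
                            {
                                "parameter": param,
                                "test": f"bootstrap[{term}]",
                                "name": res.name,
                                "statistic": res.statistic,
                                "df": str(res.df),
                                "p_value": res.p_value,
                                "transform": res.transform,
                                "groups": term,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort simulator (unit level)

def simulate_layer_units(
    seed: int,
    n_wt: int = 55,
    n_cko: int = 54,
    amplitude_means: tuple[float, float] = (0.499, 0.597),
    amplitude_se: tuple[float, float] = (0.020, 0.031),
    dn_latency_means: tuple[float, float] = (0.0150, 0.0125),
    dn_latency_se: tuple[float, float] = (0.0005, 0.0005),
    female_fraction: float = 0.43,
) -> pd.DataFrame:
    """Simulate a cohort of layer-average units at the printed group scales.

    Standard errors of group means convert to unit-level SDs as
    SD = SE * sqrt(n).  Units are spread over the four (residence,
    stimulation) layer combinations in a balanced rotation; amplitudes in
    % dF/F, distance-normalized latency in ms/um (drawn truncated at 0).
    """
    rng = np.random.default_rng(seed)
    rows = []
    combos = [("L2/3", "L2/3"), ("L2/3", "L4"), ("L4", "L2/3"), ("L4", "L4")]
    for geno, n, amp_mu, amp_se, lat_mu, lat_se in (
        ("WT", n_wt, amplitude_means[0], amplitude_se[0], dn_latency_means[0], dn_latency_se[0]),
        ("cKO", n_cko, amplitude_means[1], amplitude_se[1], dn_latency_means[1], dn_latency_se[1]),
    ):
        amp_sd = amp_se * np.sqrt(n)
        lat_sd = lat_se * np.sqrt(n)
        for i in range(n):
            res, stim = combos[i % 4]
            amp = rng.normal(amp_mu, amp_sd)
            lat = rng.normal(lat_mu, lat_sd)
            while amp <= 0:
                amp = rng.normal(amp_mu, amp_sd)
            while lat <= 0:
                lat = rng.normal(lat_mu, lat_sd)
            rows.append(
                {
                    "slice_id": f"{geno}_{i:03d}",
                    "genotype": geno,
                    "sex": "F" if rng.uniform() < female_fraction else "M",
                    "residence_layer": res,
                    "stimulation_layer": stim,
                    "n_cells": 8,
                    "amplitude_pct": amp,
                    "dn_latency_ms_per_um": lat,
                }
            )
    return pd.DataFrame(rows)
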