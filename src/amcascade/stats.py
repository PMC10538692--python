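"""Group and dyad statistics for the rhythm features.

The analysis design compares two groups of speech samples (Analysis 1:
autistic vs neurotypical respondents' own speech; Analysis 2: the
questioner's AUT-directed vs NT-directed speech) on per-rhythm frequency
power and on per-pair directed transfer entropy, then asks whether a
questioner's prosody tracks their respondent's across dyads.

Primary inference is permutation-based: group labels are shuffled across
units with each unit's within-factor profile kept intact, which makes the
tests exact under exchangeability without sphericity assumptions.  A
Greenhouse-Geisser-corrected mixed ANOVA is reported alongside for
comparability with conventional practice.  Dyadic association uses a
one-tailed (positive) Pearson or Spearman correlation, the choice gated by
a Shapiro-Wilk normality test; per-level contrasts are Benjamini-Hochberg
adjusted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests


class StatsValidationError(ValueError):
    pass


@dataclass
class StatResult:
    """One test: statistic, p, effect size, and optional BH-adjusted p."""

    test_name: str
    statistic: float
    p_value: float
    effect_size: float = np.nan
    tails: str = "two"
    adjusted_p: float | None = None
    method: str = ""
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "tails": self.tails,
            "adjusted_p": self.adjusted_p,
            "method": self.method,
            "n": self.n,
        }


RHYTHM_POWER_COLS = ["prosody_power", "syllable_power", "phoneme_power"]


def te_feature_columns(pairs=("prosody_syllable", "prosody_phoneme", "syllable_phoneme")):
    return [f"te_{p}_{d}" for p in pairs for d in ("top_down", "bottom_up")]


def build_feature_table(manifest: pd.DataFrame, power_rows: list,
                        te_tables: list) -> pd.DataFrame:
    """Assemble the per-sample feature table.

    One row per sample: identity columns from the manifest, the three
    rhythm powers, and the six TE columns (pair x direction).
    """
    powers = pd.DataFrame(power_rows)
    te_all = pd.concat(te_tables, ignore_index=True)
    te_wide = (
        te_all.assign(col="te_" + te_all["pair"] + "_" + te_all["direction"])
        .pivot_table(index="sample_id", columns="col", values="te_bits")
        .reset_index()
    )
    id_cols = [c for c in ("sample_id", "speaker_id", "role", "group",
                           "direction_label", "dyad_id") if c in manifest.columns]
    powers = powers.drop(
        columns=[c for c in id_cols if c in powers.columns and c != "sample_id"]
    )
    table = manifest[id_cols].merge(powers, on="sample_id").merge(
        te_wide, on="sample_id"
    )
    te_cols = te_feature_columns()
    missing = [c for c in RHYTHM_POWER_COLS + te_cols if c not in table.columns]
    if missing:
        raise StatsValidationError(f"feature table missing columns: {missing}")
    return table


def speaker_average(table: pd.DataFrame, unit_col: str = "speaker_id") -> pd.DataFrame:
    """Mean of every feature per unit x direction_label.

    The unit defaults to the speaker; passing ``unit_col='dyad_id'``
    aggregates per conversational pair instead, which is the exchangeable
    unit when the same few questioners appear in every dyad.
    """
    if unit_col not in table.columns:
        raise StatsValidationError(f"table needs a {unit_col} column")
    num_cols = [c for c in table.columns
                if pd.api.types.is_numeric_dtype(table[c])]
    keep = [c for c in ("group", "speaker_id", "dyad_id") if c in table.columns
            and c != unit_col]
    agg = {c: "mean" for c in num_cols} | {c: "first" for c in keep}
    return (
        table.groupby([unit_col, "direction_label"], as_index=False)
        .agg(agg)
    )


def normality_gate(values, alpha: float = 0.05) -> StatResult:
    """Shapiro-Wilk normality test; gates the dyad-correlation method."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        raise StatsValidationError("Shapiro-Wilk needs n >= 3")
    if np.ptp(v) == 0:
        raise StatsValidationError("constant input: normality undefined")
    w, p = sst.shapiro(v)
    return StatResult(
        test_name="shapiro_wilk",
        statistic=float(w),
        p_value=float(p),
        method="spearman" if p < alpha else "pearson",
        n=v.size,
    )


def _corr_stat(x, y, method):
    if method == "spearman":
        return float(sst.spearmanr(x, y).statistic)
    return float(sst.pearsonr(x, y).statistic)


def _exact_perm_p(x, y, method, observed):
    """Exact one-tailed (greater) permutation p over all n! pairings."""
    n = len(x)
    if method == "spearman":
        xv = sst.rankdata(x)
        yv = sst.rankdata(y)
    else:
        xv = np.asarray(x, dtype=np.float64)
        yv = np.asarray(y, dtype=np.float64)
    xv = (xv - xv.mean()) / xv.std()
    yv = (yv - yv.mean()) / yv.std()
    obs_dot = float(xv @ yv)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        d = float(xv[list(perm)] @ yv)
        count += d >= obs_dot - 1e-12
        total += 1
    return count / total


def dyad_correlation(questioner_values, respondent_values,
                     method: str = "auto", alpha: float = 0.05) -> StatResult:
    """One-tailed positive correlation between dyad partners.

    ``method='auto'`` uses Pearson unless Shapiro-Wilk rejects normality
    for either margin (then Spearman).  The p-value is an exact pairing
    permutation p for n <= 10 and the asymptotic one-tailed p otherwise.
    """
    q = np.asarray(questioner_values, dtype=np.float64)
    r = np.asarray(respondent_values, dtype=np.float64)
    if q.size != r.size:
        raise StatsValidationError("paired inputs must have equal length")
    n = q.size
    if n < 4:
        raise StatsValidationError("need at least 4 dyads")
    if method == "auto":
        p_q = normality_gate(q, alpha).p_value
        p_r = normality_gate(r, alpha).p_value
        method = "spearman" if min(p_q, p_r) < alpha else "pearson"
    if method == "spearman":
        ranks = sst.rankdata(q)
        if np.unique(ranks).size < n:
            warnings.warn("ties present: using average ranks", stacklevel=2)
    stat = _corr_stat(q, r, method)
    if n <= 10:
        p = _exact_perm_p(q, r, method, stat)
    elif method == "spearman":
        p = float(sst.spearmanr(q, r, alternative="greater").pvalue)
    else:
        p = float(sst.pearsonr(q, r, alternative="greater").pvalue)
    return StatResult(
        test_name="dyad_correlation",
        statistic=stat,
        p_value=p,
        effect_size=stat,
        tails="one",
        method=method,
        n=n,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise StatsValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _interaction_stat(z, groups):
    """Between-group profile divergence: sum over levels of centered
    group-mean differences squared (levels standardized beforehand)."""
    a = z[groups]
    b = z[~groups]
    delta = a.mean(axis=0) - b.mean(axis=0)
    return float(((delta - delta.mean()) ** 2).sum())


def group_contrast(
    table: pd.DataFrame,
    level_cols,
    group_col: str = "group_label",
    n_permutations: int = 1000,
    seed: int = 0,
    parametric: bool = True,
) -> list:
    """Permutation interaction test plus per-level group contrasts.

    ``table`` has one row per unit (speaker or sample) with a two-level
    ``group_col`` and one column per within-factor level.  Group labels are
    permuted across units with each unit's profile kept intact.  Per-level
    two-sided contrasts of group means are BH-adjusted.  A Greenhouse-
    Geisser-corrected mixed ANOVA is appended for reference when pingouin
    is importable and the design is estimable.
    """
    level_cols = list(level_cols)
    labels = table[group_col].to_numpy()
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise StatsValidationError(f"{group_col} must have exactly 2 levels, got {uniq}")
    groups = labels == uniq[0]
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise StatsValidationError("each group needs >= 2 units")
    X = table[level_cols].to_numpy(dtype=np.float64)
    n = X.shape[0]
    # standardize levels so the interaction statistic weighs them equally
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    obs_inter = _interaction_stat(Z, groups)
    obs_diffs = X[groups].mean(axis=0) - X[~groups].mean(axis=0)

    count_inter = 1
    counts_lvl = np.ones(len(level_cols))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        g = groups[perm]
        count_inter += _interaction_stat(Z, g) >= obs_inter - 1e-12
        d = X[g].mean(axis=0) - X[~g].mean(axis=0)
        counts_lvl += np.abs(d) >= np.abs(obs_diffs) - 1e-12
    p_inter = count_inter / (n_permutations + 1)
    p_lvls = counts_lvl / (n_permutations + 1)
    adj = fdr_adjust(p_lvls)

    pooled_sd = np.sqrt(
        ((groups.sum() - 1) * X[groups].var(axis=0, ddof=1)
         + ((~groups).sum() - 1) * X[~groups].var(axis=0, ddof=1))
        / (n - 2)
    )
    pooled_sd[pooled_sd == 0] = np.nan

    results = [
        StatResult(
            test_name="interaction_permutation",
            statistic=obs_inter,
            p_value=float(p_inter),
            method=f"permutation({n_permutations})",
            n=n,
        )
    ]
    for j, col in enumerate(level_cols):
        results.append(
            StatResult(
                test_name=f"contrast_{col}",
                statistic=float(obs_diffs[j]),
                p_value=float(p_lvls[j]),
                effect_size=float(obs_diffs[j] / pooled_sd[j]),
                adjusted_p=float(adj[j]),
                method=f"permutation({n_permutations})",
                n=n,
            )
        )
    if parametric:
        par = _parametric_reference(table, level_cols, group_col)
        if par is not None:
            results.append(par)
    return results


def _parametric_reference(table, level_cols, group_col):
    """GG-corrected mixed ANOVA interaction via pingouin, if available."""
    try:
        import pingouin as pg
    except Exception:  # pragma: no cover - pingouin is normally installed
        return None
    long = table.reset_index(names="_unit").melt(
        id_vars=["_unit", group_col],
        value_vars=level_cols,
        var_name="level",
        value_name="value",
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(
                data=long, dv="value", within="level",
                subject="_unit", between=group_col, correction=True,
            )
        row = aov[aov["Source"] == "Interaction"].iloc[0]
        p_val = np.nan
        for col in ("p_GG_corr", "p-GG-corr", "p_unc", "p-unc"):
            if col in aov.columns and np.isfinite(row.get(col, np.nan)):
                p_val = float(row[col])
                break
        return StatResult(
            test_name="interaction_mixed_anova",
            statistic=float(row["F"]),
            p_value=p_val,
            effect_size=float(row.get("np2", np.nan)),
            method="mixed_anova_gg",
            n=int(table.shape[0]),
        )
    except Exception:
        return None


def results_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def analysis_tables(feature_table: pd.DataFrame):
    """Split the feature table into the two analysis designs.

    Analysis 1 contrasts AUT_speech vs NT_speech (respondents' own speech);
    Analysis 2 contrasts AUT_directed vs NT_directed (questioner speech).
    Adds a two-level ``group_label`` column to each.
    """
    a1 = feature_table[
        feature_table.direction_label.isin(["AUT_speech", "NT_speech"])
    ].copy()
    a2 = feature_table[
        feature_table.direction_label.isin(["AUT_directed", "NT_directed"])
    ].copy()
    a1["group_label"] = a1.direction_label
    a2["group_label"] = a2.direction_label
    return a1, a2
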