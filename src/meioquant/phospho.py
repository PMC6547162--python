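"""Per-residue aggregation of label-free peptide intensities.

The pericentromeric pool of the meiotic kleisin (Rec8) is isolated by
immunoprecipitating shugoshin (Sgo1); the phosphorylation state of the
co-precipitated kleisin is then compared between strains.  Because a
residue can be observed in several peptides (variable modifications,
mis-cleavage), quantification proceeds residue-by-residue:

1. intensities are normalized per (condition, replicate) by a factor
   derived from peptides of a co-precipitating reference protein
   (Sgo1-bound Smc3), cancelling IP efficiency differences;
2. for each residue, the intensities of all observed peptides whose
   span contains it are summed (phospho- and nonphosphopeptides are
   aggregated separately, mirroring the TiO2 eluate / flow-through
   split);
3. the per-replicate log2 ratio of mutant over wild-type sums is taken;
4. replicate ratios are averaged and tested against 0 with a two-sided
   one-sample t-test (significance at p < 0.05).

Missing intensities are excluded rather than zero-imputed: a zero would
poison the logarithms, and the residue simply has no observation in
that sample.

Tables are tidy :class:`pandas.DataFrame` objects with columns
``peptide_id, start, end, phospho_state, condition, replicate,
intensity`` (spans are 1-based inclusive on the target protein).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PHOSPHO = "phosphopeptide"
NONPHOSPHO = "nonphosphopeptide"

PEPTIDE_COLUMNS = [
    "peptide_id", "start", "end", "phospho_state",
    "condition", "replicate", "intensity",
]


def _validate_peptides(df: pd.DataFrame, protein_length: int | None = None) -> pd.DataFrame:
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table lacks columns {missing}")
    if (df["start"] > df["end"]).any():
        raise ValueError("peptide span start must be <= end")
    if (df["start"] < 1).any():
        raise ValueError("peptide spans are 1-based; start must be >= 1")
    if protein_length is not None and (df["end"] > protein_length).any():
        raise ValueError("peptide span exceeds protein length")
    return df


def norm_factor(
    reference_peptides: pd.DataFrame, baseline_condition: str = "WT"
) -> dict[tuple[str, str], float]:
    """Per-(condition, replicate) normalization factors from a reference
    protein.

    factor(s, r) = sum of reference intensities in (s, r) divided by the
    sum in (baseline, r); baseline factors are 1 by construction.
    Dividing a sample's intensities by its factor makes the reference
    protein equal across conditions within each replicate.
    """
    df = reference_peptides.dropna(subset=["intensity"])
    sums = df.groupby(["condition", "replicate"])["intensity"].sum()
    conditions = df["condition"].unique()
    replicates = df["replicate"].unique()
    if baseline_condition not in conditions:
        raise ValueError(f"baseline condition {baseline_condition!r} has no reference peptides")
    factors: dict[tuple[str, str], float] = {}
    for cond in conditions:
        for rep in replicates:
            if (cond, rep) not in sums.index or (baseline_condition, rep) not in sums.index:
                raise ValueError(
                    f"reference peptides missing for condition {cond!r}, replicate {rep!r}"
                )
            factors[(cond, rep)] = float(
                sums[(cond, rep)] / sums[(baseline_condition, rep)]
            )
    return factors


def per_residue_sum(
    peptides: pd.DataFrame,
    factors: dict[tuple[str, str], float] | None,
    protein_length: int,
) -> pd.DataFrame:
    """Normalized per-residue intensity sums.

    For every residue i, condition s, replicate r and phospho state, the
    values of all observed peptides whose span contains i are summed
    after dividing each intensity by factor(s, r).  Residues covered by
    no peptide are absent from the output (missing, not zero).

    Returns a tidy frame with columns ``residue, condition, replicate,
    phospho_state, value``.
    """
    df = _validate_peptides(peptides, protein_length).dropna(subset=["intensity"]).copy()
    if df.empty:
        raise ValueError("peptide table has no observed intensities")
    if factors is not None:
        fac = df.apply(lambda r: factors[(r["condition"], r["replicate"])], axis=1)
        df["intensity"] = df["intensity"] / fac
    df["residue"] = [
        range(int(s), int(e) + 1) for s, e in zip(df["start"], df["end"])
    ]
    long = df.explode("residue")
    long["residue"] = long["residue"].astype(int)
    out = (
        long.groupby(["residue", "condition", "replicate", "phospho_state"])["intensity"]
        .sum()
        .reset_index()
        .rename(columns={"intensity": "value"})
    )
    return out


def residue_log2_ratio(
    sums: pd.DataFrame, condition: str, baseline: str = "WT"
) -> pd.DataFrame:
    """Per-replicate log2 ratios of per-residue sums, condition/baseline.

    ratio(i, r) = log2 value(i, condition, r) - log2 value(i, baseline, r).
    A residue missing on either side in a replicate yields no row; zero
    sums (log undefined) are likewise dropped, flagged in the
    ``undefined`` companion count returned as a DataFrame attribute.
    """
    wide = sums.pivot_table(
        index=["residue", "replicate", "phospho_state"],
        columns="condition",
        values="value",
        aggfunc="first",
    )
    for c in (condition, baseline):
        if c not in wide.columns:
            raise ValueError(f"condition {c!r} absent from sums")
    pair = wide[[condition, baseline]].dropna()
    nonpos = (pair[condition] <= 0) | (pair[baseline] <= 0)
    pair = pair[~nonpos]
    out = pair.reset_index()
    out["log2_ratio"] = np.log2(out[condition]) - np.log2(out[baseline])
    out = out[["residue", "replicate", "phospho_state", "log2_ratio"]]
    out.attrs["n_undefined"] = int(nonpos.sum())
    return out


@dataclass
class ResidueRatio:
    """Replicate-averaged log2 fold change for one residue."""

    residue: int
    phospho_state: str
    mean: float
    sd: float | None
    n: int
    t: float | None
    p: float | None
    significant: bool
    degenerate: bool  # zero replicate variance: t undefined


def average_and_test(ratios: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Average replicate log2 ratios per residue and test mean != 0.

    Uses a two-sided one-sample t-test where n >= 2; zero-variance
    replicate sets are flagged degenerate (no p-value) and n = 1 yields
    a mean with null sd and p.  Returns one row per (residue,
    phospho_state) with columns matching :class:`ResidueRatio`.
    """
    rows = []
    for (residue, state), grp in ratios.groupby(["residue", "phospho_state"]):
        vals = grp["log2_ratio"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else None
        t = p = None
        degenerate = False
        if n >= 2:
            if sd == 0.0:
                degenerate = True
            else:
                res = stats.ttest_1samp(vals, 0.0)
                t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "residue": int(residue),
                "phospho_state": state,
                "mean": mean,
                "sd": sd,
                "n": n,
                "t": t,
                "p": p,
                "significant": (p is not None and p < alpha),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).sort_values(["phospho_state", "residue"]).reset_index(drop=True)


def per_residue_pipeline(
    peptides: pd.DataFrame,
    reference_peptides: pd.DataFrame,
    protein_length: int,
    condition: str,
    baseline: str = "WT",
) -> pd.DataFrame:
    """Full aggregation: normalize, sum per residue, ratio, average, test."""
    factors = norm_factor(reference_peptides, baseline)
    sums = per_residue_sum(peptides, factors, protein_length)
    ratios = residue_log2_ratio(sums, condition, baseline)
    return average_and_test(ratios)


def western_ratio(
    target_strain: float,
    target_wt: float,
    loading_strain: float,
    loading_wt: float,
) -> float:
    """Loading-control-corrected western-blot double ratio.

    (target_strain / target_wt) divided by the corresponding ratio of
    the loading-control signal (e.g. Kar2), per quantitative-western
    convention.  All four signals must be positive.
    """
    for name, v in (
        ("target_strain", target_strain),
        ("target_wt", target_wt),
        ("loading_strain", loading_strain),
        ("loading_wt", loading_wt),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return float((target_strain / target_wt) / (loading_strain / loading_wt))
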