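"""Trait matrices, assemblage weights, and community-weighted moments.

For trait j and window (site) k the two functional indices are

    CWM_jk = sum_i P_ik * trait_ij
    CWV_jk = sum_i P_ik * trait_ij**2 - CWM_jk**2

where P_ik is species i's weight in window k — either presence/absence
(equal weights over the species present) or its occurrence rate (relative
frequency over the window's pooled survey quadrats/points). Weights are
normalised to sum to 1 within a window so the CWM is a genuine weighted
mean (richness-independent) under both schemes.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WEIGHTING_MODES = ("presence_absence", "occurrence_rate")

#: relative tolerance for clamping tiny negative CWVs born of
#: floating-point cancellation in the one-pass identity
CWV_CLAMP_RTOL = 1e-12


# ---------------------------------------------------------------------------
# trait matrix construction


def impute_traits(
    records: pd.DataFrame, trait_columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Build a complete species x trait matrix from raw trait records.

    ``records`` is long or semi-long: columns ``species``, ``genus``, then
    one column per trait, possibly with several rows per species and with
    missing values. Resolution order per (species, trait):

    1. several values available -> their mean;
    2. no species-level value -> mean over congeners (genus-mean imputation);
    3. neither -> the species is dropped with a logged warning.

    Returns the trait matrix (indexed by species, with ``genus`` retained)
    and a report dict with the imputed fraction and dropped species.
    """
    if trait_columns is None:
        trait_columns = [
            c for c in records.columns if c not in ("species", "genus")
        ]
    by_species = records.groupby("species").agg(
        {"genus": "first", **{t: "mean" for t in trait_columns}}
    )
    n_values = len(by_species) * len(trait_columns)
    missing = by_species[list(trait_columns)].isna()
    genus_means = by_species.groupby("genus")[list(trait_columns)].mean()
    filled = by_species.copy()
    for t in trait_columns:
        needs = missing[t]
        if needs.any():
            filled.loc[needs, t] = genus_means.loc[
                by_species.loc[needs, "genus"], t
            ].to_numpy()
    still_missing = filled[list(trait_columns)].isna().any(axis=1)
    dropped = list(filled.index[still_missing])
    if dropped:
        log.warning(
            "dropping %d species with no species- or genus-level trait data: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
    matrix = filled.loc[~still_missing]
    report = {
        "n_species": len(matrix),
        "n_dropped": len(dropped),
        "dropped": dropped,
        "imputed_fraction": float(
            (missing & ~still_missing.to_numpy()[:, None]).to_numpy().sum()
            / max(n_values, 1)
        ),
    }
    return matrix, report


def check_trait_correlations(
    matrix: pd.DataFrame,
    trait_columns: Sequence[str] | None = None,
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Spearman correlations among traits over species; warn above threshold.

    Redundant traits (|rho| > 0.7) would double-weight one functional axis;
    pairs involving a constant trait are undefined and reported NaN.
    """
    if trait_columns is None:
        trait_columns = [
            c
            for c in matrix.columns
            if c not in ("genus",) and np.issubdtype(matrix[c].dtype, np.number)
        ]
    sub = matrix[list(trait_columns)]
    if len(sub) < 3:
        raise ValueError("need at least 3 species")
    corr = sub.corr(method="spearman")
    for c in trait_columns:
        if sub[c].nunique() <= 1:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    flagged = []
    cols = list(trait_columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            rho = corr.iloc[i, j]
            if np.isfinite(rho) and abs(rho) > threshold:
                flagged.append((cols[i], cols[j], float(rho)))
                warnings.warn(
                    f"traits {cols[i]!r} and {cols[j]!r} correlate at "
                    f"rho={rho:.2f} (> {threshold})",
                    stacklevel=2,
                )
    return corr, flagged


# ---------------------------------------------------------------------------
# assemblage weights


def build_weights(surveys: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Per-window species weights P_ik under the requested weighting scheme.

    ``occurrence_rate``: P_ik = count_ik / sum_i count_ik;
    ``presence_absence``: P_ik = 1/n over the n species with count > 0.
    Windows with no recorded species are excluded (logged). Weights sum to 1
    within every window.
    """
    if mode not in WEIGHTING_MODES:
        raise ValueError(f"mode must be one of {WEIGHTING_MODES}, got {mode!r}")
    df = surveys[surveys["count"] > 0].copy()
    empty = set(surveys["window"].unique()) - set(df["window"].unique())
    if empty:
        log.info("excluding %d windows with no species recorded", len(empty))
    if mode == "occurrence_rate":
        totals = df.groupby("window")["count"].transform("sum")
        df["weight"] = df["count"] / totals
    else:
        sizes = df.groupby("window")["species"].transform("size")
        df["weight"] = 1.0 / sizes
    return df[["window", "species", "weight"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# community-weighted moments (array core + table API)


def weighted_moments(weights: np.ndarray, traits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CWM and CWV for one assemblage, vectorised over trait columns.

    ``weights``: (n_species,), summing to 1. ``traits``: (n_species,) or
    (n_species, n_traits). CWV uses the one-pass identity
    ``E[x^2] - E[x]^2`` with negative cancellation residue clamped to 0.
    """
    t = np.atleast_2d(np.asarray(traits, dtype=float).T).T  # (n, T)
    w = np.asarray(weights, dtype=float)
    cwm = w @ t
    cwv = w @ (t * t) - cwm**2
    scale2 = np.max(np.abs(t), axis=0) ** 2
    tol = CWV_CLAMP_RTOL * np.where(scale2 > 0, scale2, 1.0)
    cwv = np.where(cwv > 0, cwv, np.where(cwv > -tol, 0.0, cwv))
    return cwm, np.maximum(cwv, 0.0)


def _aligned_traits(
    weights: pd.DataFrame, matrix: pd.DataFrame, traits: Sequence[str]
) -> pd.DataFrame:
    missing = set(weights["species"]) - set(matrix.index)
    if missing:
        raise KeyError(
            "species missing from trait matrix: " + ", ".join(sorted(missing)[:10])
        )
    return matrix.loc[weights["species"], list(traits)]


def cwm(weights: pd.DataFrame, matrix: pd.DataFrame, trait: str) -> pd.Series:
    """Community-weighted mean of one trait per window."""
    t = _aligned_traits(weights, matrix, [trait]).to_numpy().ravel()
    out = (
        pd.DataFrame({"window": weights["window"], "wx": weights["weight"] * t})
        .groupby("window")["wx"]
        .sum()
    )
    out.name = trait
    return out


def cwv(weights: pd.DataFrame, matrix: pd.DataFrame, trait: str) -> pd.Series:
    """Community-weighted variance of one trait per window (clamped >= 0)."""
    t = _aligned_traits(weights, matrix, [trait]).to_numpy().ravel()
    w = weights["weight"].to_numpy()
    df = pd.DataFrame(
        {"window": weights["window"], "wx": w * t, "wx2": w * t * t}
    )
    agg = df.groupby("window").sum()
    v = agg["wx2"] - agg["wx"] ** 2
    scale2 = max(float(np.max(np.abs(t)) ** 2), 1.0) if len(t) else 1.0
    tol = CWV_CLAMP_RTOL * scale2
    if (v < -tol).any():
        warnings.warn("CWV below -tol: clamping larger-than-roundoff negative")
    v = v.clip(lower=0.0)
    v.name = trait
    return v


def functional_index_table(
    surveys: pd.DataFrame,
    matrix: pd.DataFrame,
    traits: Sequence[str],
    modes: Iterable[str] = WEIGHTING_MODES,
) -> pd.DataFrame:
    """Long table of CWM/CWV/richness per window x trait x weighting mode."""
    frames = []
    richness = (
        surveys[surveys["count"] > 0].groupby("window")["species"].nunique()
    )
    for mode in modes:
        w = build_weights(surveys, mode)
        for trait in traits:
            m = cwm(w, matrix, trait)
            v = cwv(w, matrix, trait)
            frames.append(
                pd.DataFrame(
                    {
                        "window": m.index,
                        "trait": trait,
                        "mode": mode,
                        "cwm": m.to_numpy(),
                        "cwv": v.to_numpy(),
                        "richness": richness.loc[m.index].to_numpy(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
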