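"""Per-country, per-scenario assemblage trait summaries.

Works on pandas tables with documented column contracts rather than bespoke
record classes:

* palm table — ``species``, ``genus``, ``fruit_length_cm`` (NaN allowed before
  gap-filling), plus bookkeeping columns ``excluded`` (bool),
  ``exclusion_reason`` and ``filled`` (bool) added by the operations here.
* frugivore/mammal table — ``species``, ``family``, ``mass_kg``, ``diet``
  (one of ``frugivore_primary``, ``frugivore_secondary``, ``herbivore``,
  ``other``), ``status`` (``extant`` | ``extinct``), ``iucn``.
* checklist — ``species``, ``country``, ``present`` (0/1); mammal checklists
  additionally carry ``scenario`` (``current`` | ``present_natural``).

The assemblage "maximum" is a robust maximum: the 95th percentile across
member species, computed on the natural scale (log transforms happen at the
modelling stage). Medians accompany every maximum.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FRUGIVORE_DIETS = {"frugivore_primary", "frugivore_secondary"}
TIERS = ("liberal", "default", "conservative")

#: Palm species excluded from aggregation by default: a naturally occurring
#: sterile hybrid, plus three species whose fruits are water-dispersed and
#: rarely taken by animals.
DEFAULT_PALM_EXCLUSIONS = (
    "Butyagrus nabonnandii",
    "Cocos nucifera",
    "Lodoicea maldivica",
    "Nypa fruticans",
)


def percentile_95(values, q: float = 95.0) -> float:
    """Linear-interpolation percentile (plotting position h = (n-1)p + 1).

    This is numpy's default quantile rule; a single value or constant list
    returns that value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take a percentile of an empty collection")
    return float(np.percentile(arr, q))


def fill_fruit_gaps(palms: pd.DataFrame) -> pd.DataFrame:
    """Fill missing fruit lengths with the unweighted mean of measured congenerics.

    Species with no measured congeneric are dropped with a warning. Filled
    records are flagged in a boolean ``filled`` column.
    """
    out = palms.copy()
    if "filled" not in out.columns:
        out["filled"] = False
    missing = out["fruit_length_cm"].isna()
    if not missing.any():
        return out
    genus_means = out.loc[~missing].groupby("genus")["fruit_length_cm"].mean()
    fill = out.loc[missing, "genus"].map(genus_means)
    unfillable = missing & out["genus"].map(lambda g: g not in genus_means.index)
    if unfillable.any():
        dropped = out.loc[unfillable, "species"].tolist()
        warnings.warn(
            f"dropping {len(dropped)} species with no measured congeneric: {dropped}",
            stacklevel=2,
        )
    out.loc[missing, "fruit_length_cm"] = fill
    out.loc[missing & ~unfillable, "filled"] = True
    return out.loc[~unfillable].reset_index(drop=True)


def apply_exclusions(palms: pd.DataFrame,
                     exclusion_list=DEFAULT_PALM_EXCLUSIONS) -> pd.DataFrame:
    """Flag named species as excluded; they stay in the table for provenance
    but are skipped by :func:`summarize_assemblages`.

    Names absent from the table raise a warning, not an error.
    """
    out = palms.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["exclusion_reason"] = ""
    names = set(exclusion_list)
    absent = names - set(out["species"])
    if absent:
        warnings.warn(f"exclusion names not found in palm table: {sorted(absent)}",
                      stacklevel=2)
    hit = out["species"].isin(names)
    out.loc[hit, "excluded"] = True
    out.loc[hit, "exclusion_reason"] = "listed exclusion"
    return out


def family_frugivory_fractions(mammals: pd.DataFrame) -> pd.Series:
    """Proportion of extant species in each family whose diet is frugivorous."""
    extant = mammals[mammals["status"] == "extant"]
    return extant.groupby("family")["diet"].apply(
        lambda d: d.isin(FRUGIVORE_DIETS).mean()
    )


def classify_extinct_frugivores(extinct: pd.DataFrame,
                                family_fractions: pd.Series | dict,
                                overrides: dict[str, set[str]] | None,
                                tier: str) -> pd.DataFrame:
    """Select extinct taxa counted as frugivores under a classification tier.

    All tiers require a predominantly herbivorous diet. On top of that:

    * ``liberal`` — no further condition;
    * ``default`` — family frugivory fraction >= 0.40, or an explicit
      paleo-diet override naming the species for this tier;
    * ``conservative`` — family frugivory fraction >= 0.50.

    Tier membership is nested: conservative <= default <= liberal. Taxa from
    unknown families with no override are excluded with a warning.
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}")
    fracs = pd.Series(family_fractions, dtype=float)
    overrides = overrides or {}

    herb = extinct["diet"] == "herbivore"
    frac = extinct["family"].map(fracs)
    has_override = extinct["species"].map(
        lambda s: tier in overrides.get(s, set())
    )
    unknown = frac.isna() & ~extinct["species"].isin(overrides)
    if (herb & unknown).any():
        warnings.warn(
            "excluding extinct herbivores from unknown families with no override: "
            f"{extinct.loc[herb & unknown, 'species'].tolist()}",
            stacklevel=2,
        )
    frac = frac.fillna(0.0)
    if tier == "liberal":
        keep = herb
    elif tier == "conservative":
        keep = herb & (frac >= 0.50)
    else:
        keep = herb & ((frac >= 0.40) | has_override)
    return extinct.loc[keep].reset_index(drop=True)


def summarize_assemblages(palm_checklist: pd.DataFrame,
                          mammal_checklist: pd.DataFrame,
                          palms: pd.DataFrame,
                          mammals: pd.DataFrame,
                          scenario: str = "current",
                          tier: str = "default",
                          overrides: dict[str, set[str]] | None = None,
                          regions: pd.Series | dict | None = None,
                          quantile: float = 95.0) -> pd.DataFrame:
    """Per-country trait summaries for one faunal scenario.

    ``current`` uses extant frugivores and current presences; the
    counterfactual ``present_natural`` adds extinct taxa passing the chosen
    classification tier, with present-natural presences. Countries with no
    extant frugivore, or no palm, are dropped with a warning in either
    scenario.

    Returns one row per retained country with columns ``country``, ``region``
    (if supplied), ``scenario``, ``max_fruit_cm``, ``med_fruit_cm``,
    ``max_body_kg``, ``med_body_kg`` (maxima are the robust 95th-percentile
    kind), the true maxima ``abs_max_fruit_cm``/``abs_max_body_kg`` used by
    the true-max defaunation variant, ``n_palms``, ``n_frugivores``.
    """
    if scenario not in ("current", "present_natural"):
        raise ValueError("scenario must be 'current' or 'present_natural'")

    active_palms = palms.copy()
    if "excluded" in active_palms.columns:
        active_palms = active_palms[~active_palms["excluded"]]
    active_palms = active_palms.dropna(subset=["fruit_length_cm"])

    extant_frug = mammals[(mammals["status"] == "extant")
                          & mammals["diet"].isin(FRUGIVORE_DIETS)]
    frug = extant_frug
    if scenario == "present_natural":
        extinct = mammals[mammals["status"] == "extinct"]
        fracs = family_frugivory_fractions(mammals)
        passing = classify_extinct_frugivores(extinct, fracs, overrides, tier)
        frug = pd.concat([extant_frug, passing], ignore_index=True)

    palm_present = palm_checklist[(palm_checklist["present"] == 1)
                                  & palm_checklist["species"].isin(active_palms["species"])]
    mam_rows = mammal_checklist[mammal_checklist["scenario"] == scenario] \
        if "scenario" in mammal_checklist.columns else mammal_checklist
    mam_present = mam_rows[(mam_rows["present"] == 1)
                           & mam_rows["species"].isin(frug["species"])]
    # countries must hold at least one *extant* frugivore in any scenario
    extant_rows = mammal_checklist[mammal_checklist["scenario"] == "current"] \
        if "scenario" in mammal_checklist.columns else mammal_checklist
    countries_with_extant = set(
        extant_rows[(extant_rows["present"] == 1)
                    & extant_rows["species"].isin(extant_frug["species"])]["country"]
    )

    fruit_by_sp = active_palms.set_index("species")["fruit_length_cm"]
    mass_by_sp = frug.set_index("species")["mass_kg"]

    rows = []
    all_countries = sorted(set(palm_checklist["country"]) | set(mammal_checklist["country"]))
    dropped_no_frug, dropped_no_palm = [], []
    palm_groups = palm_present.groupby("country")["species"]
    mam_groups = mam_present.groupby("country")["species"]
    for country in all_countries:
        palm_sp = palm_groups.get_group(country) if country in palm_groups.groups else pd.Series([], dtype=object)
        if len(palm_sp) == 0:
            dropped_no_palm.append(country)
            continue
        if country not in countries_with_extant:
            dropped_no_frug.append(country)
            continue
        mam_sp = mam_groups.get_group(country) if country in mam_groups.groups else pd.Series([], dtype=object)
        if len(mam_sp) == 0:
            dropped_no_frug.append(country)
            continue
        fruits = fruit_by_sp.loc[palm_sp.unique()].to_numpy()
        masses = mass_by_sp.loc[mam_sp.unique()].to_numpy()
        rows.append({
            "country": country,
            "scenario": scenario if scenario == "current" else f"present_natural({tier})",
            "max_fruit_cm": percentile_95(fruits, quantile),
            "med_fruit_cm": float(np.median(fruits)),
            "max_body_kg": percentile_95(masses, quantile),
            "med_body_kg": float(np.median(masses)),
            "abs_max_fruit_cm": float(fruits.max()),
            "abs_max_body_kg": float(masses.max()),
            "n_palms": int(len(palm_sp.unique())),
            "n_frugivores": int(len(mam_sp.unique())),
        })
    if dropped_no_palm:
        warnings.warn(f"dropped {len(dropped_no_palm)} countries with no palms",
                      stacklevel=2)
    if dropped_no_frug:
        warnings.warn(
            f"dropped {len(dropped_no_frug)} countries with no extant frugivores",
            stacklevel=2)
    out = pd.DataFrame(rows)
    if regions is not None and not out.empty:
        out.insert(1, "region", out["country"].map(pd.Series(regions)))
    return out
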