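"""Synthetic worlds with known ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised and validated without any data
download:

* country centroids scattered on a projected plane, split into three
  "regions" mimicking the Afrotropics / Neotropics / Indo-Australia bands;
* six bioclim variables built from three latent Gaussian-process fields with
  distance-decaying (exponential) covariance, so spatial regression tests see
  genuinely autocorrelated climate, and LGM ensemble-mean columns offset from
  the present by a further smooth anomaly field;
* mammal species with log-normal body masses, family-structured diets,
  size-biased IUCN categories (ordinal logistic on log mass), and an extinct
  cohort drawn from an upward-shifted mass distribution so that the
  counterfactual present-natural scenario carries heavier assemblages —
  mirroring the strongly size-selective character of Late Pleistocene
  extinction;
* palm species whose fruit lengths are tuned so that each country's
  95th-percentile log fruit length follows
  ``alpha + coupling_beta * (95th-percentile log body mass) + climate terms
  + noise``, the exact relationship the modelling stage estimates;
* Red List transition count tables simulated from a known rate matrix.

All randomness flows from a single integer seed through named child streams,
one per generator stage, so stage outputs are individually reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assemblage import percentile_95
from .redlist_ctmc import (N_CAT, RateMatrix, TransitionCountTable,
                           transition_matrix)

REGIONS = ("Afrotropics", "Neotropics", "IndoAustralia")

#: synthetic mammal families and the share of their extant species that are
#: frugivorous; spans the 0.40/0.50 tier thresholds used for extinct taxa
_FAMILY_FRUG_TARGET = {
    "Fam01": 0.90, "Fam02": 0.80, "Fam03": 0.70, "Fam04": 0.60,
    "Fam05": 0.55, "Fam06": 0.50, "Fam07": 0.45, "Fam08": 0.40,
    "Fam09": 0.30, "Fam10": 0.20, "Fam11": 0.10, "Fam12": 0.00,
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Generating parameters; defaults approximate the study conditions
    (about 130 countries, ~2500 palms, size-selective extinction)."""

    n_countries: int = 129
    n_palm_species: int = 2400
    n_mammal_species: int = 1800
    coupling_beta: float = 0.6
    fruit_lognormal_params: tuple[float, float] = (np.log(6.0), 0.35)  # (mu log cm, within-country sd)
    mass_lognormal_params: tuple[float, float] = (-1.0, 1.8)           # log kg
    climate_range_scale: float = 250.0                                 # km, field correlation length
    extinct_megafauna_fraction: float = 0.12
    size_risk_slope: float = 0.8
    fruit_noise_sd: float = 0.15       # country-level noise on log 95th-pct fruit
    climate_effects: tuple[float, float] = (0.15, 0.10)  # latent fields 1 and 3 on log fruit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 2 or self.n_palm_species < 1 or self.n_mammal_species < 1:
            raise ValueError("counts must be positive (and >= 2 countries)")
        if not 0 <= self.extinct_megafauna_fraction <= 1:
            raise ValueError("extinct_megafauna_fraction must lie in [0, 1]")
        if self.climate_range_scale <= 0 or self.fruit_noise_sd < 0:
            raise ValueError("scale parameters must be nonnegative")
        if self.fruit_lognormal_params[1] <= 0 or self.mass_lognormal_params[1] <= 0:
            raise ValueError("log-normal sigmas must be positive")
        int(self.seed)  # raises if not integer-like


@dataclass
class SyntheticWorld:
    """All pipeline inputs plus the generating truth."""

    palms: pd.DataFrame
    mammals: pd.DataFrame
    palm_checklist: pd.DataFrame
    mammal_checklist: pd.DataFrame
    centroids: pd.DataFrame     # country, x, y, region
    climate: pd.DataFrame       # country, bio1..bio6, bio1_lgm_mean, bio4_lgm_mean
    truth: dict
    config: SyntheticWorldConfig


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(s) for name, s in zip(names, children)}


def generate_spatial_field(centroids, range_scale: float,
                           seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Zero-mean unit-variance Gaussian process with exponential covariance
    exp(-d / range_scale) over the supplied (x, y) centroids.

    Duplicate centroids (singular covariance) are jittered by a tiny amount
    with a warning.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two centroids")
    if range_scale <= 0:
        raise ValueError("range_scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    if np.any(d[~np.eye(len(pts), dtype=bool)] == 0):
        warnings.warn("duplicate centroids jittered before covariance build",
                      stacklevel=2)
        pts = pts + rng.normal(scale=1e-6 * (1 + pts.std()), size=pts.shape)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    cov = np.exp(-d / range_scale)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(pts)))
    return chol @ rng.standard_normal(len(pts))


def generate_transition_counts(q: RateMatrix, n_species: int, elapsed_years: float,
                               start_distribution, seed: int | None = None,
                               label: str = "synthetic") -> TransitionCountTable:
    """Simulate a Red List transition count table from a known rate matrix.

    Each species draws a start category from ``start_distribution`` and an
    end category from the matching row of ``P(elapsed_years)``.
    """
    if n_species < 1:
        raise ValueError("n_species must be positive")
    start = np.asarray(start_distribution, dtype=float)
    if start.shape != (N_CAT,) or not np.isclose(start.sum(), 1.0):
        raise ValueError(f"start_distribution must be {N_CAT} probabilities summing to 1")
    rng = np.random.default_rng(seed)
    p = transition_matrix(q, elapsed_years)
    starts = rng.multinomial(n_species, start)
    counts = np.zeros((N_CAT, N_CAT), dtype=np.int64)
    for i in range(N_CAT):
        if starts[i] > 0:
            counts[i] = rng.multinomial(starts[i], p[i])
    return TransitionCountTable(counts, elapsed_years, label=label)


def _make_climate(centroids: pd.DataFrame, cfg: SyntheticWorldConfig,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Six bioclim columns from three latent fields (plus LGM means).

    Loadings keep >90% of variance in three components; units are arbitrary
    but plausible (deg C, mm)."""
    xy = centroids[["x", "y"]].to_numpy()
    latents = np.column_stack([
        generate_spatial_field(xy, cfg.climate_range_scale, rng) for _ in range(3)
    ])
    l1, l2, l3 = latents.T
    eps = rng.standard_normal((len(xy), 6)) * 0.15
    bio = pd.DataFrame({
        "bio1": 22 + 4 * l1 + 0.6 * eps[:, 0],                    # mean annual temp, C
        "bio2": 30 + 8 * (0.75 * l1 + 0.66 * l2) + 1.2 * eps[:, 1],  # temp seasonality
        "bio3": 15 + 5 * (0.9 * l1 - 0.3 * l2) + 0.8 * eps[:, 2],    # coldest-quarter temp
        "bio4": 1800 + 600 * l2 + 90 * eps[:, 3],                  # annual precip, mm
        "bio5": 55 + 15 * (0.55 * l2 + 0.8 * l3) + 2.4 * eps[:, 4],  # precip seasonality
        "bio6": 140 + 60 * (0.4 * l2 + 0.85 * l3) + 9 * eps[:, 5],   # driest-quarter precip
    }, index=centroids["country"])
    temp_anom = 3.5 + 1.2 * generate_spatial_field(xy, cfg.climate_range_scale, rng)
    prec_anom = 250 + 120 * generate_spatial_field(xy, cfg.climate_range_scale, rng)
    bio["bio1_lgm_mean"] = bio["bio1"] - temp_anom
    bio["bio4_lgm_mean"] = bio["bio4"] - prec_anom
    return bio.reset_index(), latents


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Build a fully coupled synthetic world; see the module docstring."""
    cfg = config
    rngs = _streams(int(cfg.seed),
                    ["centroids", "climate", "mammals", "iucn", "presence", "palms"])

    # --- countries ----------------------------------------------------------
    n_c = cfg.n_countries
    countries = [f"C{i:03d}" for i in range(n_c)]
    rng = rngs["centroids"]
    xy = rng.uniform(0, 1000, size=(n_c, 2))
    region = np.array(REGIONS)[np.minimum((xy[:, 0] // (1000 / 3)).astype(int), 2)]
    centroids = pd.DataFrame({"country": countries, "x": xy[:, 0], "y": xy[:, 1],
                              "region": region})

    climate, latents = _make_climate(centroids, cfg, rngs["climate"])

    # --- mammals ------------------------------------------------------------
    rng = rngs["mammals"]
    mu_m, sd_m = cfg.mass_lognormal_params
    fams = list(_FAMILY_FRUG_TARGET)
    n_ext = cfg.n_mammal_species
    fam_extant = rng.choice(fams, size=n_ext)
    log_mass = rng.normal(mu_m, sd_m, size=n_ext)
    frug_p = np.array([_FAMILY_FRUG_TARGET[f] for f in fam_extant])
    is_frug = rng.uniform(size=n_ext) < frug_p
    diet = np.where(is_frug,
                    np.where(rng.uniform(size=n_ext) < 0.6,
                             "frugivore_primary", "frugivore_secondary"),
                    np.where(rng.uniform(size=n_ext) < 0.6, "herbivore", "other"))
    mammals = pd.DataFrame({
        "species": [f"Mammal_{i:04d}" for i in range(n_ext)],
        "family": fam_extant,
        "mass_kg": np.exp(log_mass),
        "diet": diet,
        "status": "extant",
    })

    n_gone = int(round(cfg.extinct_megafauna_fraction * n_ext))
    if n_gone:
        # extinct cohort: masses shifted up ~ e^4 (size-selective extinction),
        # families biased toward frugivorous clades, overwhelmingly herbivorous
        fam_gone = rng.choice(fams[:8], size=n_gone)
        extinct = pd.DataFrame({
            "species": [f"Extinct_{i:04d}" for i in range(n_gone)],
            "family": fam_gone,
            "mass_kg": np.exp(rng.normal(mu_m + 4.0, 1.2, size=n_gone)),
            "diet": np.where(rng.uniform(size=n_gone) < 0.9, "herbivore", "other"),
            "status": "extinct",
        })
        mammals = pd.concat([mammals, extinct], ignore_index=True)

    # --- IUCN categories: ordinal logistic in standardized log mass ---------
    rng = rngs["iucn"]
    extant_mask = mammals["status"] == "extant"
    lm = np.log(mammals.loc[extant_mask, "mass_kg"].to_numpy())
    zm = (lm - lm.mean()) / lm.std(ddof=1)
    latent = cfg.size_risk_slope * zm + rng.logistic(size=extant_mask.sum())
    thresholds = np.array([0.6, 1.5, 2.3, 3.1])
    cat_idx = (latent[:, None] > thresholds[None, :]).sum(axis=1)
    iucn = np.array(["LC", "NT", "VU", "EN", "CR"])[cat_idx]
    dd = rng.uniform(size=len(iucn)) < 0.04
    iucn = np.where(dd, "DD", iucn)
    mammals["iucn"] = "EX"
    mammals.loc[extant_mask, "iucn"] = iucn

    # --- presence-absence checklists ----------------------------------------
    # species occupy the countries inside a disk around a range center (real
    # ranges are spatially contiguous, so assemblage composition — and with
    # it the 95th-percentile body mass — varies smoothly in space), thinned
    # by independent Bernoulli draws tied to country richness multipliers
    rng = rngs["presence"]
    rho = np.exp(rng.normal(0, 0.4, size=n_c))           # country richness multipliers
    dists = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    frug_mask = mammals["diet"].isin(["frugivore_primary", "frugivore_secondary"]).to_numpy()
    n_frug_extant = int((frug_mask & extant_mask.to_numpy()).sum())

    def _range_presence(n_species: int, mean_range_countries: float) -> np.ndarray:
        centers = rng.choice(n_c, size=n_species, p=rho / rho.sum())
        # disk radius giving ~mean_range_countries occupied units on average
        base_r = 1000.0 * np.sqrt(mean_range_countries / (np.pi * n_c))
        radius = base_r * np.exp(rng.normal(0, 0.4, size=n_species))
        inside = dists[centers] <= radius[:, None]
        keep = rng.uniform(size=(n_species, n_c)) < np.minimum(1.0, rho)[None, :]
        return inside & keep

    mean_range_extant = 45.0 * n_c / max(n_frug_extant, 1)
    pres_extant = _range_presence(n_ext, mean_range_extant)
    # force >= 1 extant frugivore everywhere
    frug_rows = np.flatnonzero(frug_mask[:n_ext])
    for c in range(n_c):
        if not pres_extant[frug_rows, c].any():
            pres_extant[rng.choice(frug_rows), c] = True

    mam_rows = []
    sp_ext = mammals.loc[extant_mask, "species"].to_numpy()
    for c, country in enumerate(countries):
        for s in np.flatnonzero(pres_extant[:, c]):
            mam_rows.append((sp_ext[s], country, 1, "current"))
            mam_rows.append((sp_ext[s], country, 1, "present_natural"))
    if n_gone:
        pres_gone = _range_presence(n_gone, 18.0 * n_c / n_gone)
        sp_gone = mammals.loc[~extant_mask, "species"].to_numpy()
        for c, country in enumerate(countries):
            for s in np.flatnonzero(pres_gone[:, c]):
                mam_rows.append((sp_gone[s], country, 1, "present_natural"))
    mammal_checklist = pd.DataFrame(mam_rows,
                                    columns=["species", "country", "present", "scenario"])

    # realized current assemblage maxima drive the fruit coupling
    frug_extant_idx = np.flatnonzero(frug_mask[:n_ext])
    masses = mammals["mass_kg"].to_numpy()[:n_ext]
    log_m95 = np.empty(n_c)
    for c in range(n_c):
        present = frug_extant_idx[pres_extant[frug_extant_idx, c]]
        log_m95[c] = np.log(percentile_95(masses[present]))

    # --- palms ---------------------------------------------------------------
    rng = rngs["palms"]
    mu_f, sd_w = cfg.fruit_lognormal_params
    g1, g3 = cfg.climate_effects
    alpha = mu_f - cfg.coupling_beta * log_m95.mean()
    noise = rng.normal(0, cfg.fruit_noise_sd, size=n_c)
    target = (alpha + cfg.coupling_beta * log_m95
              + g1 * latents[:, 0] + g3 * latents[:, 2] + noise)

    n_p = cfg.n_palm_species
    # milder richness gradient than for mammals: every country keeps enough
    # endemic palms for its percentile to be locally controlled
    w_home = np.sqrt(rho)
    home = rng.choice(n_c, size=n_p, p=w_home / w_home.sum())
    # offset so the home-country 95th percentile of fruit lengths ~ exp(target)
    z95 = 1.6448536269514722
    log_fruit = rng.normal(target[home] - z95 * sd_w, sd_w)
    # genera are geographically coherent (a few genera per home country), so
    # congeneric-mean gap filling stays local and preserves country signal
    genus = np.array([f"Genus{home[i]:03d}{rng.integers(3)}" for i in range(n_p)])
    species_names = np.array([f"Palm_{i:04d}" for i in range(n_p)])

    palm_rows = [(species_names[i], countries[home[i]], 1) for i in range(n_p)]
    # sparse spillover into the home country's nearest neighbors (ranges are
    # spatially contiguous, so shared species sit in adjacent units); only
    # small-fruited palms spread — large-fruited species are dispersal
    # limited, which is the size-matching premise itself
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    nearest = np.argsort(d2, axis=1)[:, :3]
    home_median = np.array([
        np.median(log_fruit[home == c]) if np.any(home == c) else np.inf
        for c in range(n_c)
    ])
    small_fruited = log_fruit < home_median[home]
    n_spill = np.where(small_fruited, rng.poisson(0.3, size=n_p), 0)
    occupants: list[list[int]] = [[] for _ in range(n_c)]
    for i in range(n_p):
        occupants[home[i]].append(i)
    for i in np.flatnonzero(n_spill):
        for c in rng.choice(nearest[home[i]], size=min(n_spill[i], 3), replace=False):
            palm_rows.append((species_names[i], countries[c], 1))
            occupants[c].append(i)
    # calibrate fruit lengths so the *realized* assemblage 95th percentile
    # follows the generating relation: shared species mix neighbors' palms
    # into each country's percentile, so home fruits are shifted by the
    # residual to the target, iterated to a fixed point
    occ = [np.unique(o) for o in occupants]
    realized = np.empty(n_c)
    for _ in range(8):
        realized = np.array([
            np.log(np.percentile(np.exp(log_fruit[o]), 95)) for o in occ
        ])
        log_fruit += (target - realized)[home]
    realized = np.array([
        np.log(np.percentile(np.exp(log_fruit[o]), 95)) for o in occ
    ])

    palms = pd.DataFrame({
        "species": species_names,
        "genus": genus,
        "fruit_length_cm": np.exp(log_fruit),
    })
    # knock out ~8% of fruit lengths to exercise congeneric gap-filling
    gaps = rng.uniform(size=n_p) < 0.08
    palms.loc[gaps, "fruit_length_cm"] = np.nan
    # the four default-excluded species, present in a few countries each;
    # the sterile hybrid has no fruit record and no congeners (gets dropped)
    special = pd.DataFrame({
        "species": ["Cocos nucifera", "Lodoicea maldivica", "Nypa fruticans",
                    "Butyagrus nabonnandii"],
        "genus": ["Cocos", "Lodoicea", "Nypa", "Butyagrus"],
        "fruit_length_cm": [25.0, 30.0, 12.0, np.nan],
    })
    palms = pd.concat([palms, special], ignore_index=True)
    for sp in special["species"]:
        for c in rng.choice(n_c, size=3, replace=False):
            palm_rows.append((sp, countries[c], 1))
    palm_checklist = pd.DataFrame(palm_rows, columns=["species", "country", "present"])
    palm_checklist = palm_checklist.drop_duplicates(ignore_index=True)

    truth = {
        "alpha": float(alpha),
        "coupling_beta": float(cfg.coupling_beta),
        "climate_effects": {"latent1": g1, "latent3": g3},
        "fruit_noise_sd": float(cfg.fruit_noise_sd),
        "log_m95_current": pd.Series(log_m95, index=countries),
        "target_log_fruit95": pd.Series(target, index=countries),
        "latent_fields": pd.DataFrame(latents, index=countries,
                                      columns=["latent1", "latent2", "latent3"]),
        "realized_log_fruit95": pd.Series(realized, index=countries),
        "size_risk_slope": float(cfg.size_risk_slope),
    }
    return SyntheticWorld(palms=palms, mammals=mammals,
                          palm_checklist=palm_checklist,
                          mammal_checklist=mammal_checklist,
                          centroids=centroids, climate=climate,
                          truth=truth, config=cfg)
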