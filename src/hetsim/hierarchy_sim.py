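"""Hierarchical Gaussian generator for multi-site animal-behavior data.

Each animal's score on a trait decomposes as

    score = beta0 + site_effect + subject_effect + residual

with ``site_effect ~ N(0, sigma_L)`` shared by every animal at a site,
``subject_effect ~ N(0, sigma_S)`` per subject, and an independent
residual ``~ N(0, sigma_e)``.  Subjects are nested within sites, so the
intraclass correlation is ``sigma_L**2 / (sigma_L**2 + sigma_S**2 +
sigma_e**2)``; it governs how misleading one-site-per-group sampling is.

Populations are returned as tidy :class:`pandas.DataFrame` tables, one
row per (animal, trait), carrying the realized effect components so the
decomposition is exactly reconstructible per record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Column order of the tidy animal-score table.
SCORE_COLUMNS = [
    "group",
    "site_id",
    "subject_id",
    "trait",
    "score",
    "site_effect",
    "subject_effect",
    "residual",
]


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters for one trait.

    Parameters
    ----------
    name : str
        Trait label (e.g. ``"neophobia"``).
    beta0 : float
        Population grand mean, in score units.
    sigma_L : float
        Between-site SD (shared location effect), same units as ``beta0``.
    sigma_S : float
        Between-subject SD within a site.
    sigma_e : float
        Residual (within-subject measurement) SD.

    Notes
    -----
    With one observation per subject, ``sigma_S`` and ``sigma_e`` are not
    separately identifiable from data; both are kept because the model is
    stated with both, and the per-record decomposition exercises them
    jointly.  Only their sum of squares matters for any sampling
    distribution derived here.
    """

    name: str
    beta0: float
    sigma_L: float
    sigma_S: float
    sigma_e: float

    def __post_init__(self) -> None:
        for field in ("sigma_L", "sigma_S", "sigma_e"):
            value = getattr(self, field)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"{field} must be finite and >= 0, got {value!r} "
                    f"for trait {self.name!r}"
                )
        if not np.isfinite(self.beta0):
            raise ValueError(f"beta0 must be finite, got {self.beta0!r}")

    @property
    def total_variance(self) -> float:
        """sigma_L**2 + sigma_S**2 + sigma_e**2."""
        return self.sigma_L**2 + self.sigma_S**2 + self.sigma_e**2

    @property
    def within_site_variance(self) -> float:
        """sigma_S**2 + sigma_e**2 (variance of animals around their site mean)."""
        return self.sigma_S**2 + self.sigma_e**2

    @property
    def icc(self) -> float:
        """Intraclass correlation: between-site share of total variance."""
        total = self.total_variance
        return self.sigma_L**2 / total if total > 0 else 0.0


@dataclass(frozen=True)
class GroupSpec:
    """A group (population) of animals: a label plus one TraitSpec per trait."""

    name: str
    traits: tuple[TraitSpec, ...]

    def __init__(self, name: str, traits: Sequence[TraitSpec]) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "traits", tuple(traits))
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate trait names in group {name!r}: {names}")
        if not self.traits:
            raise ValueError(f"group {name!r} has no traits")

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(f"group {self.name!r} has no trait {name!r}")

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]


def simulate_population(
    group: GroupSpec,
    n_sites: int,
    n_per_site: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate a multi-site population of animals for every trait in ``group``.

    One site effect is drawn per (site, trait); one subject effect and one
    residual per (subject, trait).  Traits are drawn independently of each
    other.  Returns ``n_sites * n_per_site`` rows per trait in
    :data:`SCORE_COLUMNS` order; ``site_id`` and ``subject_id`` are 0-based
    and ``subject_id`` is unique within its site only.
    """
    if n_sites < 1 or n_per_site < 1:
        raise ValueError(
            f"n_sites and n_per_site must be >= 1, got {n_sites}, {n_per_site}"
        )
    n_total = n_sites * n_per_site
    site_ids = np.repeat(np.arange(n_sites), n_per_site)
    subject_ids = np.tile(np.arange(n_per_site), n_sites)

    frames = []
    for spec in group.traits:
        site_draw = rng.normal(0.0, spec.sigma_L, size=n_sites)
        subject_effect = rng.normal(0.0, spec.sigma_S, size=n_total)
        residual = rng.normal(0.0, spec.sigma_e, size=n_total)
        site_effect = site_draw[site_ids]
        frames.append(
            pd.DataFrame(
                {
                    "group": group.name,
                    "site_id": site_ids,
                    "subject_id": subject_ids,
                    "trait": spec.name,
                    "score": spec.beta0 + site_effect + subject_effect + residual,
                    "site_effect": site_effect,
                    "subject_effect": subject_effect,
                    "residual": residual,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]


def sample_site(population: pd.DataFrame, rng: np.random.Generator) -> int:
    """Pick one site uniformly at random from a simulated population.

    Sampling is with replacement across calls: two independent calls may
    return the same site.
    """
    if len(population) == 0:
        raise ValueError("cannot sample a site from an empty population")
    sites = np.unique(population["site_id"].to_numpy())
    return int(rng.choice(sites))


def sample_animals(
    population: pd.DataFrame,
    site_id: int,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample ``n`` distinct subjects (all their trait records) from one site."""
    at_site = population[population["site_id"] == site_id]
    if len(at_site) == 0:
        raise ValueError(f"site {site_id} not present in population")
    subjects = np.unique(at_site["subject_id"].to_numpy())
    if n > len(subjects):
        raise ValueError(
            f"requested {n} animals but site {site_id} has only {len(subjects)}"
        )
    chosen = rng.choice(subjects, size=n, replace=False)
    return at_site[at_site["subject_id"].isin(chosen)].reset_index(drop=True)


def draw_group_sample(
    group: GroupSpec,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a one-site sample of ``n`` animals directly from the model.

    Distributional shortcut for the full population -> random site ->
    random animals pipeline: one fresh site effect per trait, ``n`` fresh
    subjects.  The sample mean therefore has variance
    ``sigma_L**2 + (sigma_S**2 + sigma_e**2) / n`` around ``beta0`` — the
    site effect does not average away, which is the crux of the
    one-site-per-group design.
    """
    if n < 2:
        raise ValueError(f"group sample needs n >= 2, got {n}")
    frames = []
    for spec in group.traits:
        scores, site_eff, subj_eff, resid = _draw_trait_sample(spec, n, rng)
        frames.append(
            pd.DataFrame(
                {
                    "group": group.name,
                    "site_id": 0,
                    "subject_id": np.arange(n),
                    "trait": spec.name,
                    "score": scores,
                    "site_effect": site_eff,
                    "subject_effect": subj_eff,
                    "residual": resid,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]


def _draw_trait_sample(
    spec: TraitSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One fresh site, n fresh subjects, for a single trait (array form)."""
    site = rng.normal(0.0, spec.sigma_L)
    subj = rng.normal(0.0, spec.sigma_S, size=n)
    resid = rng.normal(0.0, spec.sigma_e, size=n)
    site_eff = np.full(n, site)
    return spec.beta0 + site_eff + subj + resid, site_eff, subj, resid


def _draw_trait_sample_matrix(
    spec: TraitSpec, n_reps: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_reps, n) score matrix: one fresh site per row. Vectorized engine
    behind the Monte-Carlo module; row i is distributed exactly like
    :func:`_draw_trait_sample` with its own site."""
    site = rng.normal(0.0, spec.sigma_L, size=(n_reps, 1))
    subj = rng.normal(0.0, spec.sigma_S, size=(n_reps, n))
    resid = rng.normal(0.0, spec.sigma_e, size=(n_reps, n))
    return spec.beta0 + site + subj + resid


def estimate_variance_components(
    population: pd.DataFrame, trait: str
) -> dict[str, float]:
    """Method-of-moments variance decomposition of a balanced population.

    Returns estimates of the between-site variance ``sigma_L**2`` and the
    within-site variance ``sigma_S**2 + sigma_e**2`` (the two quantities
    identifiable from one observation per subject), plus the grand mean.
    The between-site estimate subtracts the within-site contribution
    ``sigma_W**2 / m`` from the variance of site means (m = site size),
    so it is unbiased for balanced designs but can come out negative by
    chance when the true sigma_L is near zero.
    """
    sub = population[population["trait"] == trait]
    if len(sub) == 0:
        raise ValueError(f"trait {trait!r} not present in population")
    by_site = sub.groupby("site_id")["score"]
    sizes = by_site.size()
    if sizes.nunique() != 1:
        raise ValueError("variance decomposition requires balanced site sizes")
    m = int(sizes.iloc[0])
    site_means = by_site.mean()
    sigma2_within = float(by_site.var(ddof=1).mean()) if m > 1 else float("nan")
    var_site_means = float(site_means.var(ddof=1)) if len(site_means) > 1 else 0.0
    sigma2_between = var_site_means - sigma2_within / m
    return {
        "grand_mean": float(sub["score"].mean()),
        "sigma2_between": sigma2_between,
        "sigma2_within": sigma2_within,
        "n_sites": int(len(site_means)),
        "n_per_site": m,
    }
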