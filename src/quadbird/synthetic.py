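"""Synthetic quadrat communities with known (stored) ground truth.

The generator emulates a town-scale breeding-bird quadrat survey: 30 quadrats
of 25 ha (10 urban, 20 peri-/extra-urban), 8 land-cover categories summing to
the quadrat area, ~36 species whose occupancy responds (nonlinearly) to land
cover, two sampling sessions with imperfect per-pair detection, and a subset
of late-arriving migrants absent from the first session.

Two regimes matter for testing:

* ``filtering_strength = 0`` — a *null world*: every species has the same
  occupancy probability at every quadrat (site equivalence), so the
  environmental-filtering test should reject at its nominal rate only.
* ``filtering_strength > 0`` — land cover filters the community; rejection
  power grows with the strength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .survey import (
    DEFAULT_QUADRAT_AREA,
    LANDCOVER_CATEGORIES,
    N_LANDCOVER,
    QuadratRecord,
    SurveySession,
    Zone,
    landcover_matrix,
    write_landcover_table,
    write_survey,
)

# Zone-conditional Dirichlet concentrations for land-cover allocation.
# Urban quadrats are dominated by built classes (continuous/discontinuous
# fabric + roads, ~80% on average); peri-/extra-urban by arable land and
# ligneous crops.  Order follows LANDCOVER_CATEGORIES.
ZONE_DIRICHLET = {
    Zone.URBAN: np.array([0.5, 5.0, 5.0, 1.5, 0.2, 0.3, 2.5, 0.5]),
    Zone.PERI_URBAN: np.array([6.0, 0.8, 1.5, 0.5, 0.3, 2.5, 0.8, 0.6]),
    Zone.EXTRA_URBAN: np.array([7.0, 0.4, 1.0, 0.3, 0.3, 3.0, 0.6, 0.4]),
}


@dataclass(frozen=True)
class EffectSpec:
    """One smooth land-cover effect on the logit-occupancy scale.

    kind: 'linear'     -> amplitude * (x / area)
          'saturating' -> amplitude * x / (x + half_sat)
          'bump'       -> amplitude * exp(-(x - center)^2 / (2 width^2))
    """

    kind: str
    amplitude: float
    center: float = 0.0
    width: float = 1.0
    half_sat: float = 1.0

    def __call__(self, x: np.ndarray, area: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.amplitude * (x / area)
        if self.kind == "saturating":
            return self.amplitude * x / (x + self.half_sat)
        if self.kind == "bump":
            return self.amplitude * np.exp(
                -((x - self.center) ** 2) / (2.0 * self.width**2)
            )
        raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth occupancy/abundance profile of one synthetic species."""

    species_id: str
    occupancy_intercept: float  # logit scale
    landcover_effects: tuple[EffectSpec | None, ...]  # one per category
    abundance_mean_scale: float  # expected pairs where present (> 0)
    session2_only: bool = False

    def __post_init__(self):
        if self.abundance_mean_scale <= 0:
            raise ValueError("abundance_mean_scale must be positive")
        if len(self.landcover_effects) != N_LANDCOVER:
            raise ValueError(
                f"need {N_LANDCOVER} effect slots "
                f"(None where a category has no effect)"
            )


@dataclass
class GeneratorConfig:
    """Settings for one synthetic community."""

    n_urban: int = 10
    n_peri_extra: int = 20
    quadrat_area: float = DEFAULT_QUADRAT_AREA
    n_species: int = 36
    filtering_strength: float = 3.0
    p_detect: float = 0.9
    abundance_model: str = "ztpoisson"  # or "negbin"
    nb_dispersion: float = 1.5  # negbin size parameter (smaller = more spread)
    frac_session2_only: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.filtering_strength < 0:
            raise ValueError("filtering_strength must be >= 0")
        if not (0 < self.p_detect <= 1):
            raise ValueError("p_detect must be in (0, 1]")
        if self.abundance_model not in ("ztpoisson", "negbin"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if self.n_urban < 0 or self.n_peri_extra < 0:
            raise ValueError("quadrat counts must be >= 0")


@dataclass
class SyntheticCommunity:
    """A generated survey plus its ground truth."""

    quadrats: list[QuadratRecord]
    sessions: list[SurveySession]
    profiles: list[SpeciesProfile]
    occupancy_prob: np.ndarray  # S x Q true occupancy probabilities
    true_presence: np.ndarray  # S x Q realized presence (before detection)
    config: GeneratorConfig
    seed: int


def generate_landcover(
    n_urban: int,
    n_peri_extra: int,
    quadrat_area: float = DEFAULT_QUADRAT_AREA,
    seed: int = 0,
) -> list[QuadratRecord]:
    """Zone-conditional Dirichlet allocation of land cover, scaled to area."""
    rng = np.random.default_rng(seed)
    n_peri = n_peri_extra // 2
    zones = (
        [Zone.URBAN] * n_urban
        + [Zone.PERI_URBAN] * n_peri
        + [Zone.EXTRA_URBAN] * (n_peri_extra - n_peri)
    )
    records = []
    for i, zone in enumerate(zones):
        shares = rng.dirichlet(ZONE_DIRICHLET[zone])
        lc = shares * quadrat_area
        # exact area conservation despite float rounding
        lc[-1] = quadrat_area - lc[:-1].sum()
        records.append(
            QuadratRecord(
                quadrat_id=f"Q{i + 1:02d}",
                zone=zone,
                landcover=lc,
                quadrat_area=quadrat_area,
            )
        )
    return records


def _draw_profiles(cfg: GeneratorConfig, rng: np.random.Generator) -> list[SpeciesProfile]:
    area = cfg.quadrat_area
    profiles = []
    n_migrants = int(round(cfg.frac_session2_only * cfg.n_species))
    migrant_idx = set(
        rng.choice(cfg.n_species, size=n_migrants, replace=False).tolist()
    )
    for s in range(cfg.n_species):
        n_active = rng.integers(2, 5)  # 2..4 categories shape each species
        active = rng.choice(N_LANDCOVER, size=n_active, replace=False)
        effects: list[EffectSpec | None] = [None] * N_LANDCOVER
        for k in active:
            kind = rng.choice(["linear", "saturating", "bump"])
            amp = rng.normal(0.0, 1.2)
            if kind == "bump":
                effects[k] = EffectSpec(
                    kind="bump",
                    amplitude=amp,
                    center=rng.uniform(0.1 * area, 0.7 * area),
                    width=rng.uniform(0.1 * area, 0.3 * area),
                )
            elif kind == "saturating":
                effects[k] = EffectSpec(
                    kind="saturating",
                    amplitude=amp,
                    half_sat=rng.uniform(0.05 * area, 0.4 * area),
                )
            else:
                effects[k] = EffectSpec(kind="linear", amplitude=amp)
        profiles.append(
            SpeciesProfile(
                species_id=f"sp{s + 1:02d}",
                occupancy_intercept=rng.normal(-0.6, 0.9),
                landcover_effects=tuple(effects),
                abundance_mean_scale=float(np.exp(rng.normal(1.0, 0.9))),
                session2_only=s in migrant_idx,
            )
        )
    return profiles


def occupancy_probability(
    profiles: Sequence[SpeciesProfile],
    quadrats: Sequence[QuadratRecord],
    filtering_strength: float,
) -> np.ndarray:
    """True S x Q occupancy probabilities implied by profiles and land cover."""
    x = landcover_matrix(quadrats)  # Q x 8
    area = quadrats[0].quadrat_area if quadrats else DEFAULT_QUADRAT_AREA
    logits = np.empty((len(profiles), x.shape[0]))
    for i, p in enumerate(profiles):
        eta = np.full(x.shape[0], p.occupancy_intercept)
        for k, eff in enumerate(p.landcover_effects):
            if eff is not None:
                eta = eta + filtering_strength * eff(x[:, k], area)
        logits[i] = eta
    return 1.0 / (1.0 + np.exp(-logits))


def _zero_truncated_counts(
    mean: np.ndarray, model: str, nb_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Counts >= 1 with the given untruncated mean, by inverse-CDF truncation."""
    mean = np.asarray(mean, dtype=float)
    out = np.ones(mean.shape, dtype=np.int64)
    if mean.size == 0:
        return out
    if model == "ztpoisson":
        p0 = np.exp(-mean)
        u = rng.uniform(p0, 1.0)
        out = stats.poisson.ppf(u, mean).astype(np.int64)
    else:  # negbin parameterized by size n and mean mu
        n = nb_size
        p = n / (n + mean)
        p0 = p**n
        u = rng.uniform(p0, 1.0)
        out = stats.nbinom.ppf(u, n, p).astype(np.int64)
    return np.maximum(out, 1)


def generate_community(config: GeneratorConfig) -> SyntheticCommunity:
    """Generate land cover, species profiles, true presence and two sessions.

    All randomness flows from ``config.seed`` through a split seed sequence,
    so the same config reproduces identical matrices.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    lc_seed, prof_seed, occ_seed, det_seed = root.spawn(4)
    quadrats = generate_landcover(
        config.n_urban,
        config.n_peri_extra,
        config.quadrat_area,
        seed=lc_seed,
    )
    rng_prof = np.random.default_rng(prof_seed)
    profiles = _draw_profiles(config, rng_prof)
    probs = occupancy_probability(profiles, quadrats, config.filtering_strength)

    rng_occ = np.random.default_rng(occ_seed)
    presence = (rng_occ.uniform(size=probs.shape) < probs).astype(np.int8)

    means = np.array([p.abundance_mean_scale for p in profiles])
    true_pairs = np.zeros(probs.shape, dtype=np.int64)
    occupied = presence.astype(bool)
    mean_grid = np.broadcast_to(means[:, None], probs.shape)
    true_pairs[occupied] = _zero_truncated_counts(
        mean_grid[occupied], config.abundance_model, config.nb_dispersion, rng_occ
    )

    rng_det = np.random.default_rng(det_seed)
    s2_only = np.array([p.session2_only for p in profiles])
    sessions = []
    for label in (1, 2):
        detected = rng_det.binomial(true_pairs, config.p_detect)
        if label == 1:
            detected[s2_only, :] = 0
        sessions.append(
            SurveySession(
                session_label=label,
                species_ids=tuple(p.species_id for p in profiles),
                quadrat_ids=tuple(q.quadrat_id for q in quadrats),
                abundance=detected,
            )
        )

    return SyntheticCommunity(
        quadrats=quadrats,
        sessions=sessions,
        profiles=profiles,
        occupancy_prob=probs,
        true_presence=presence,
        config=config,
        seed=config.seed,
    )


def write_community(community: SyntheticCommunity, outdir) -> None:
    """Emit the CSVs the readers consume plus a ground-truth JSON sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_landcover_table(community.quadrats, outdir / "landcover.csv")
    for s in community.sessions:
        write_survey(s, outdir / f"survey_session{s.session_label}.csv")
    truth = {
        "seed": community.seed,
        "config": asdict(community.config),
        "occupancy_prob": community.occupancy_prob.tolist(),
        "true_presence": community.true_presence.tolist(),
        "profiles": [
            {
                "species_id": p.species_id,
                "occupancy_intercept": p.occupancy_intercept,
                "abundance_mean_scale": p.abundance_mean_scale,
                "session2_only": p.session2_only,
                "landcover_effects": [
                    None if e is None else asdict(e)
                    for e in p.landcover_effects
                ],
            }
            for p in community.profiles
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
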