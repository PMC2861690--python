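"""Synthetic transect generator with ground truth retained.

The generator is phenomenological: rather than simulating demography
forward in time it draws data directly from the cline structure the
analysis is designed to detect.  Two ancestral lineages diverge under a
Balding–Nichols model with a single divergence parameter ``F``; nuclear
ancestry and mtDNA lineage follow independent logistic clines along the
transect (their centers may coincide or not, producing cyto-nuclear
discordance); climate is built from one latent habitat factor that can be
flat, a gradient, or a step (ecotone); quantitative traits respond to the
habitat factor and, optionally, to lineage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    CLIMATE_VARS,
    Genotypes,
    Site,
    TransectDataset,
)

#: plausible Worldclim-like baselines for the 19 climate variables
#: (temperatures in deg C, precipitation in mm, indices unitless)
_CLIMATE_BASELINE = {
    "bio1": 25.0, "bio2": 8.0, "bio3": 75.0, "bio4": 90.0, "bio5": 31.0,
    "bio6": 20.0, "bio7": 11.0, "bio8": 25.5, "bio9": 24.5, "bio10": 26.0,
    "bio11": 24.0, "bio12": 1800.0, "bio13": 260.0, "bio14": 45.0,
    "bio15": 48.0, "bio16": 710.0, "bio17": 170.0, "bio18": 480.0,
    "bio19": 380.0,
}

#: default loading of each variable on the latent habitat factor, in
#: ln-units: wetter/cooler uphill, so precipitation loads positively and
#: temperature (weakly) negatively
_DEFAULT_LOADINGS = {
    **{f"bio{i}": -0.10 for i in range(1, 12)},
    **{f"bio{i}": 0.40 for i in range(12, 20)},
}

N_MORPH = 21
N_HUE = 6
TRAIT_COLUMNS = [f"morph_{i+1}" for i in range(N_MORPH)] + \
                [f"hue_{i+1}" for i in range(N_HUE)]


@dataclass(frozen=True)
class Cline:
    """Logistic cline along the transect: center in site units, width > 0.

    ``math.inf`` width means no cline (constant 0.5).
    """

    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("cline width must be > 0")

    def value(self, x: np.ndarray) -> np.ndarray:
        """Frequency of the *first* lineage: ~1 left of center, ~0 right."""
        x = np.asarray(x, dtype=float)
        if math.isinf(self.width):
            return np.full(x.shape, 0.5)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp((x - self.center) / self.width))


@dataclass(frozen=True)
class ClimateModel:
    """Latent habitat factor and its mapping to the 19 climate variables.

    ``profile`` is one of ``flat``, ``gradient``, ``step``.  ``magnitude``
    is the total change of the latent factor along the transect (ln-units);
    ``step_position`` locates the ecotone between two adjacent sites for the
    step profile.  ``noise_sd`` is per-variable ln-scale noise.
    """

    profile: str = "flat"
    magnitude: float = 0.0
    step_position: float = 0.5
    noise_sd: float = 0.05
    loadings: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOADINGS))
    second_factor_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.profile not in ("flat", "gradient", "step"):
            raise ValueError(f"unknown climate profile {self.profile!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def latent(self, positions: np.ndarray) -> np.ndarray:
        x = np.asarray(positions, dtype=float)
        if self.profile == "flat" or self.magnitude == 0:
            return np.zeros_like(x)
        if self.profile == "gradient":
            span = x.max() - x.min()
            if span == 0:
                return np.zeros_like(x)
            return (x - x.min()) / span * self.magnitude
        return np.where(x > self.step_position, self.magnitude, 0.0)


@dataclass(frozen=True)
class TraitModel:
    """Response of the 27 trait columns (21 morphology + 6 hue) to habitat
    and lineage, in units of the residual (within-group) SD.

    ``beta_*`` scale the latent climate factor; ``delta_*`` is the additive
    lineage effect.  ``resid_sd`` is the within-site residual SD (default 1,
    so effects are directly in within-group SD units).
    """

    beta_morph: float = 0.0
    beta_hue: float = 0.0
    delta_morph: float = 0.0
    delta_hue: float = 0.0
    resid_sd: float = 1.0


@dataclass(frozen=True)
class SimParams:
    """Full generative description of one synthetic transect."""

    n_sites: int = 8
    n_per_site: int = 48
    n_trait_per_site: int = 10
    n_loci: int = 9
    alleles_per_locus: int = 8
    divergence: float = 0.2          # Balding–Nichols F between lineages
    nuclear_cline: Cline = Cline(4.5, 0.5)
    mtdna_cline: Cline = Cline(4.5, 0.2)
    tau: float = 20.0                # ancestry concentration about site mean
    climate: ClimateModel = ClimateModel()
    traits: TraitModel = TraitModel()
    lineage_labels: tuple[str, str] = ("northwest", "central")
    geological_boundary: float | None = None   # position between two sites
    transect_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence F must be in [0, 1)")
        if self.tau <= 0:
            raise ValueError("ancestry dispersion tau must be > 0")
        if self.n_sites < 2:
            raise ValueError("need >= 2 sites")
        for c in (self.nuclear_cline, self.mtdna_cline):
            if not math.isinf(c.width) and not (
                1 - 2 <= c.center <= self.n_sites + 2
            ):
                raise ValueError("cline center far outside transect")


@dataclass
class TruthRecord:
    """Generative ground truth for one simulated transect."""

    q_true: dict[str, float]              # per genotyped individual
    site_mean_ancestry: dict[str, float]
    habitat: dict[str, str]               # per site, 'A' / 'B'
    params: SimParams

    def to_dict(self) -> dict:
        d = {
            "q_true": self.q_true,
            "site_mean_ancestry": self.site_mean_ancestry,
            "habitat": self.habitat,
            "params": asdict(self.params),
        }
        return d


def _lineage_frequencies(rng: np.random.Generator, n_loci: int, n_alleles: int,
                         F: float) -> np.ndarray:
    """Balding–Nichols draw: per locus, two lineage frequency vectors around
    a common ancestral vector with divergence ``F``.  Shape (2, L, A)."""
    anc = rng.dirichlet(np.ones(n_alleles), size=n_loci)       # (L, A)
    if F < 1e-12:
        return np.stack([anc, anc])
    conc = (1.0 - F) / F
    out = np.empty((2, n_loci, n_alleles))
    for l in range(n_loci):
        alpha = np.maximum(anc[l] * conc, 1e-9)
        out[0, l] = rng.dirichlet(alpha)
        out[1, l] = rng.dirichlet(alpha)
    return out


def simulate_transect(params: SimParams, seed: int | None = None
                      ) -> tuple[TransectDataset, TruthRecord]:
    """Draw one transect dataset plus its :class:`TruthRecord`.

    Sampling scheme: (a) lineage allele frequencies from Balding–Nichols;
    (b) site mean ancestry from the nuclear cline; (c) individual ancestry
    ``q ~ Beta(mu*tau, (1-mu)*tau)``; (d) each allele copy from lineage 1
    frequencies with probability ``q``, else lineage 2; (e) mtDNA lineage
    Bernoulli from the mtDNA cline; (f) climate from the latent habitat
    factor, loadings and ln-scale noise; (g) traits from habitat factor,
    lineage effect and residual noise.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    x = np.arange(1, params.n_sites + 1, dtype=float)
    site_ids = [f"s{i}" for i in range(1, params.n_sites + 1)]

    freqs = _lineage_frequencies(
        rng, params.n_loci, params.alleles_per_locus, params.divergence
    )
    mu = np.clip(params.nuclear_cline.value(x), 1e-9, 1 - 1e-9)
    mt_p = np.clip(params.mtdna_cline.value(x), 0.0, 1.0)

    ids, site_of, q_all, mt_lineage = [], {}, {}, {}
    calls = np.empty((params.n_sites * params.n_per_site, params.n_loci, 2),
                     dtype=np.int64)
    row = 0
    for s in range(params.n_sites):
        q = rng.beta(mu[s] * params.tau, (1 - mu[s]) * params.tau,
                     size=params.n_per_site)
        mt = rng.random(params.n_per_site) < mt_p[s]
        for j in range(params.n_per_site):
            ind = f"{site_ids[s]}_i{j + 1}"
            ids.append(ind)
            site_of[ind] = site_ids[s]
            q_all[ind] = float(q[j])
            mt_lineage[ind] = params.lineage_labels[0 if mt[j] else 1]
            # per copy: lineage of origin, then allele from that lineage
            orig = rng.random((params.n_loci, 2)) >= q[j]   # False -> lineage 1
            for l in range(params.n_loci):
                for c in range(2):
                    p = freqs[int(orig[l, c]), l]
                    calls[row, l, c] = rng.choice(params.alleles_per_locus, p=p) + 1
            row += 1

    genotypes = Genotypes(
        individual_ids=ids,
        site_of=site_of,
        loci=[f"loc{l + 1}" for l in range(params.n_loci)],
        calls=calls,
    )

    # climate
    f = params.climate.latent(x)
    loadings = np.array([params.climate.loadings[v] for v in CLIMATE_VARS])
    base = np.array([_CLIMATE_BASELINE[v] for v in CLIMATE_VARS])
    f2 = rng.normal(0.0, params.climate.second_factor_sd, size=params.n_sites) \
        if params.climate.second_factor_sd > 0 else np.zeros(params.n_sites)
    loadings2 = rng.normal(0.0, 0.1, size=len(CLIMATE_VARS)) \
        if params.climate.second_factor_sd > 0 else np.zeros(len(CLIMATE_VARS))
    eps = rng.normal(0.0, params.climate.noise_sd,
                     size=(params.n_sites, len(CLIMATE_VARS)))
    climate_vals = base[None, :] * np.exp(
        loadings[None, :] * f[:, None] + loadings2[None, :] * f2[:, None] + eps
    )

    habitat = {}
    for s, sid in enumerate(site_ids):
        if params.climate.profile == "step":
            habitat[sid] = "B" if x[s] > params.climate.step_position else "A"
        else:
            habitat[sid] = "A"

    sites = [
        Site(site_id=sid, position=float(x[s]),
             climate={v: float(climate_vals[s, k])
                      for k, v in enumerate(CLIMATE_VARS)},
             habitat=habitat[sid])
        for s, sid in enumerate(site_ids)
    ]

    # quantitative traits (separate individuals, 10 adult males per site)
    tm = params.traits
    beta = np.array([tm.beta_morph] * N_MORPH + [tm.beta_hue] * N_HUE)
    delta = np.array([tm.delta_morph] * N_MORPH + [tm.delta_hue] * N_HUE)
    traits, trait_lineage = {}, {}
    for s, sid in enumerate(site_ids):
        mt = rng.random(params.n_trait_per_site) < mt_p[s]
        vals = (
            beta[None, :] * f[s]
            + delta[None, :] * (~mt[:, None]).astype(float)
            + rng.normal(0.0, tm.resid_sd,
                         size=(params.n_trait_per_site, len(beta)))
        )
        idx = [f"{sid}_t{j + 1}" for j in range(params.n_trait_per_site)]
        traits[sid] = pd.DataFrame(vals, index=idx, columns=TRAIT_COLUMNS)
        trait_lineage[sid] = pd.Series(
            [params.lineage_labels[0 if m else 1] for m in mt], index=idx
        )

    dataset = TransectDataset(
        transect_id=params.transect_id,
        sites=sites,
        genotypes=genotypes,
        mtdna_lineage=mt_lineage,
        traits=traits,
        trait_lineage=trait_lineage,
    )
    truth = TruthRecord(
        q_true=q_all,
        site_mean_ancestry={sid: float(mu[s]) for s, sid in enumerate(site_ids)},
        habitat=habitat,
        params=params,
    )
    return dataset, truth


def scenario_preset(name: str) -> SimParams:
    """Named transect archetypes.

    ``coastal_contact``: steep, co-located nuclear and mtDNA clines at the
    geological boundary, flat climate, strong trait-lineage effect (a coastal
    secondary contact where past allopatry left a sharp signature).

    ``rainforest_ecotone``: nuclear cline centered on a climate step
    (ecotone) while the mtDNA boundary lies elsewhere — cyto-nuclear
    discordance where habitat, not history, structures the nuclear genome.

    ``mesic_contact``: shallow nuclear cline at the mtDNA boundary under a
    gentle climate gradient.

    ``control``: no clines, near-panmictic, flat climate.
    """
    if name == "coastal_contact":
        return SimParams(
            n_sites=8, divergence=0.25,
            nuclear_cline=Cline(4.5, 0.25),
            mtdna_cline=Cline(4.5, 0.15),
            tau=30.0,
            climate=ClimateModel(profile="flat", noise_sd=0.05),
            traits=TraitModel(delta_morph=2.0, delta_hue=2.0),
            lineage_labels=("northwest", "central"),
            geological_boundary=4.5,
            transect_id="coastal_contact",
        )
    if name == "rainforest_ecotone":
        return SimParams(
            n_sites=7, divergence=0.2,
            nuclear_cline=Cline(3.5, 0.3),
            mtdna_cline=Cline(5.5, 0.2),
            tau=20.0,
            climate=ClimateModel(profile="step", magnitude=0.75,
                                 step_position=3.5, noise_sd=0.08),
            traits=TraitModel(beta_morph=3.0, beta_hue=3.0),
            lineage_labels=("northwest", "central"),
            geological_boundary=5.5,
            transect_id="rainforest_ecotone",
        )
    if name == "mesic_contact":
        return SimParams(
            n_sites=9, divergence=0.15,
            nuclear_cline=Cline(5.0, 1.5),
            mtdna_cline=Cline(5.0, 0.3),
            tau=20.0,
            climate=ClimateModel(profile="gradient", magnitude=0.3,
                                 noise_sd=0.08),
            traits=TraitModel(beta_morph=1.2, beta_hue=1.2,
                              delta_morph=0.3, delta_hue=0.3),
            lineage_labels=("southwest", "central"),
            geological_boundary=5.5,
            transect_id="mesic_contact",
        )
    if name == "control":
        return SimParams(
            n_sites=5, divergence=0.02,
            nuclear_cline=Cline(3.0, math.inf),
            mtdna_cline=Cline(3.0, math.inf),
            tau=20.0,
            climate=ClimateModel(profile="flat", noise_sd=0.05),
            traits=TraitModel(),
            lineage_labels=("central", "central_minor"),
            geological_boundary=None,
            transect_id="control",
        )
    raise ValueError(f"unknown scenario preset {name!r}")


PRESETS = ("coastal_contact", "rainforest_ecotone", "mesic_contact", "control")


def two_population_genotypes(F: float, n_per_pop: int = 48, n_loci: int = 9,
                             alleles_per_locus: int = 8, seed: int = 0
                             ) -> tuple[Genotypes, np.ndarray]:
    """Two island populations fixed at ancestry 0 / 1 under Balding–Nichols
    divergence ``F`` — the canonical benchmark for ancestry estimation.

    Returns genotypes plus the true ancestry vector (1 for population A).
    """
    rng = np.random.default_rng(seed)
    freqs = _lineage_frequencies(rng, n_loci, alleles_per_locus, F)
    n = 2 * n_per_pop
    calls = np.empty((n, n_loci, 2), dtype=np.int64)
    ids, site_of = [], {}
    q_true = np.empty(n)
    for i in range(n):
        pop = 0 if i < n_per_pop else 1
        ind = f"p{pop + 1}_i{i % n_per_pop + 1}"
        ids.append(ind)
        site_of[ind] = f"pop{pop + 1}"
        q_true[i] = 1.0 - pop
        for l in range(n_loci):
            calls[i, l] = rng.choice(alleles_per_locus, size=2, p=freqs[pop, l]) + 1
    gt = Genotypes(ids, site_of, [f"loc{l + 1}" for l in range(n_loci)], calls)
    return gt, q_true
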