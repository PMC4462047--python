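"""Synthetic data generators: a toy core-carbon network with NADPH
coupling, and planted-signal FPKM time courses.

The toy network lumps the pathway blocks of de novo lipid synthesis —
glycolysis, the oxidative pentose phosphate pathway (G6PD, PGD), the
malate/pyruvate cycle (malic enzyme), TCA entry via the citrate shuttle
(ACLY), fatty acid synthesis consuming NADPH, amino-/fatty-acid export and
a biomass drain — into ~20 reactions whose LP optima are derivable by
hand, so solver behaviour can be checked against closed-form values.

The expression simulator plants a regulation table into a six-sample
(A, B, E pre; K, L, M post) FPKM matrix with multiplicative log-normal
noise, for end-to-end recovery tests of the classification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lipoflux.expression import (
    DIRECTIONS,
    STANDARD_SAMPLES,
    ExpressionMatrix,
    RegulationTable,
)
from lipoflux.model import MetabolicModel, Metabolite, Reaction, ValidationError

__all__ = [
    "ToyNetworkConfig",
    "ExpressionSimConfig",
    "toy_core_network",
    "toy_wild_type_optimum",
    "simulate_expression",
    "perturb_regulation",
]

BIG = 1000.0


@dataclass(frozen=True)
class ToyNetworkConfig:
    """Branch capacities (mmol·gDW⁻¹·h⁻¹) and couplings of the toy network.

    ``nadph_per_fas`` is the NADPH consumed per unit of fatty-acid synthesis
    flux; ``biomass_pin`` is the growth rate μ (h⁻¹) a caller typically pins
    during simulation (stored here for convenience, not baked into bounds).
    ``knock_out_me`` / ``knock_out_ppp`` zero the corresponding capacities.
    """

    glucose_uptake: float = 10.0
    ammonium_uptake: float = 5.0
    glycolysis_cap: float = BIG
    g6pd_cap: float = 100.0
    pgd_cap: float = 100.0
    me_cap: float = 2.0
    tca_cap: float = BIG
    acly_cap: float = BIG
    fas_cap: float = BIG
    aa_export_cap: float = BIG
    biomass_cap: float = BIG
    nadph_per_fas: float = 2.0
    biomass_pin: float = 0.03
    knock_out_me: bool = False
    knock_out_ppp: bool = False

    def __post_init__(self) -> None:
        caps = (
            self.glucose_uptake,
            self.ammonium_uptake,
            self.glycolysis_cap,
            self.g6pd_cap,
            self.pgd_cap,
            self.me_cap,
            self.tca_cap,
            self.acly_cap,
            self.fas_cap,
            self.aa_export_cap,
            self.biomass_cap,
        )
        if any(c < 0 for c in caps):
            raise ValidationError("capacities must be ≥ 0")
        if self.nadph_per_fas <= 0:
            raise ValidationError("nadph_per_fas must be > 0")


# biomass draw per unit growth rate (mol per mol·h⁻¹ of biomass flux)
_BIOMASS_G6P = 0.2
_BIOMASS_PYR = 0.3
_BIOMASS_ACCOA = 0.2
_BIOMASS_NH4 = 0.5


def toy_wild_type_optimum(config: ToyNetworkConfig | None = None) -> float:
    """Closed-form wild-type AA-export optimum with biomass pinned at μ.

    Derivation (defaults, objective = EX_aa, pin biomass = μ):
    let p = G6P routed through the oxidative PPP (2 NADPH per unit, the
    pentose skeleton returns as pyruvate), g = G6P through glycolysis
    (2 pyruvate per unit), m = malic-enzyme flux (1 NADPH per unit, carbon
    neutral).  Balances:

    * G6P:    uptake − 0.2 μ = p + g
    * NADPH:  nadph_per_fas · a = 2 p + m
    * pyr:    2 g + p = a + 0.2 μ (acetyl-CoA draw) + 0.3 μ

    Maximizing a with nadph_per_fas = 2 gives g = m/4 + μ/8 (0.5·(0.2+0.3)μ
    /2 with the default biomass draws → (m/2 + 0.5μ·...)/2); solving for the
    defaults: a* = (uptake − 0.2 μ) + m/2 − (m/2 + 0.5 μ)/2 where 0.5 μ is
    the pyruvate-equivalent biomass draw (0.2 + 0.3) μ.  With uptake = 10,
    μ = 0.03, m = me_cap = 2 this evaluates to 10.4865.
    """
    config = config or ToyNetworkConfig()
    mu = config.biomass_pin
    m = 0.0 if config.knock_out_me else config.me_cap
    k = config.nadph_per_fas
    ppp_cap = 0.0 if config.knock_out_ppp else min(config.g6pd_cap, config.pgd_cap)
    g6p_avail = config.glucose_uptake - _BIOMASS_G6P * mu
    pyr_biomass = (_BIOMASS_PYR + _BIOMASS_ACCOA) * mu
    # NADPH-limited optimum: a = (2p + m)/k with pyruvate closing via g
    # a = (2(g6p_avail − g) + m)/k and 2g + (g6p_avail − g) ≥ a + pyr_biomass
    # binding pyruvate constraint → g = (2 g6p_avail + m − k(g6p_avail − pyr_biomass))/(2 + k)
    g = (2.0 * g6p_avail + m - k * (g6p_avail - pyr_biomass)) / (2.0 + k)
    g = max(g, 0.0)
    p = min(g6p_avail - g, ppp_cap)
    a = (2.0 * p + m) / k
    # carbon-limited fallback when NADPH is plentiful
    a_carbon = 2.0 * g6p_avail - pyr_biomass  # everything through glycolysis
    return max(0.0, min(a, a_carbon, config.fas_cap, config.aa_export_cap))


def toy_core_network(config: ToyNetworkConfig | None = None) -> MetabolicModel:
    """Build the toy core-carbon network (21 reactions, 16 metabolites).

    Structure: glucose uptake → G6P splits between lumped glycolysis
    (G6P → 2 pyruvate) and the oxidative PPP (G6PD then PGD, one NADPH
    each; the pentose skeleton returns to pyruvate via a lumped
    non-oxidative branch).  6-phosphogluconate may also be exported, so
    G6PD remains a (halved) NADPH source when PGD is deleted.  Pyruvate
    feeds acetyl-CoA through the citrate shuttle (PC/CS/ACLY with a
    catalytic oxaloacetate pool); malic enzyme closes a carbon-neutral
    transhydrogenation cycle (PC → MDH → ME).  Fatty-acid synthesis
    consumes ``nadph_per_fas`` NADPH per unit of arachidonic acid (AA),
    which is exported by ``EX_aa`` — the reporter/objective reaction.
    NADPH is produced only by G6PD, PGD and ME.  A biomass drain consumes
    G6P, pyruvate, acetyl-CoA and ammonium.

    With the default configuration and biomass pinned at μ = 0.03 the
    wild-type AA-export optimum is 10.4865 (see
    :func:`toy_wild_type_optimum` for the closed form).  Infeasible
    configurations still return a model; infeasibility surfaces at solve
    time.
    """
    cfg = config or ToyNetworkConfig()
    g6pd_cap = 0.0 if cfg.knock_out_ppp else cfg.g6pd_cap
    pgd_cap = 0.0 if cfg.knock_out_ppp else cfg.pgd_cap
    me_cap = 0.0 if cfg.knock_out_me else cfg.me_cap
    k = cfg.nadph_per_fas

    def met(mid: str, name: str, comp: str) -> Metabolite:
        return Metabolite(id=mid, name=name, compartment=comp)

    metabolites = [
        met("glc_e", "glucose (extracellular)", "e"),
        met("glc_c", "glucose", "c"),
        met("g6p_c", "glucose 6-phosphate", "c"),
        met("p6g_c", "6-phosphogluconate", "c"),
        met("ru5p_c", "ribulose 5-phosphate", "c"),
        met("pyr_c", "pyruvate", "c"),
        met("oaa_c", "oxaloacetate", "c"),
        met("cit_c", "citrate", "c"),
        met("mal_c", "malate", "c"),
        met("accoa_c", "acetyl-CoA", "c"),
        met("aa_c", "arachidonic acid", "c"),
        met("co2_c", "carbon dioxide", "c"),
        met("nh4_e", "ammonium (extracellular)", "e"),
        met("nh4_c", "ammonium", "c"),
        met("nadp_c", "NADP+", "c"),
        met("nadph_c", "NADPH", "c"),
    ]

    def rxn(rid, name, stoich, lb, ub, gpr=None, exchange=False):
        return Reaction(
            id=rid,
            name=name,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            is_exchange=exchange,
        )

    reactions = [
        rxn("EX_glc", "glucose exchange", {"glc_e": -1}, -cfg.glucose_uptake, BIG, exchange=True),
        rxn("GLCt", "glucose transport", {"glc_e": -1, "glc_c": 1}, 0, BIG),
        rxn("HK", "hexokinase", {"glc_c": -1, "g6p_c": 1}, 0, BIG, gpr="gHK1 or gGCK"),
        rxn(
            "GLYC",
            "glycolysis (lumped)",
            {"g6p_c": -1, "pyr_c": 2},
            0,
            cfg.glycolysis_cap,
            gpr="gGLYC",
        ),
        rxn(
            "G6PD",
            "glucose-6-phosphate dehydrogenase",
            {"g6p_c": -1, "nadp_c": -1, "p6g_c": 1, "nadph_c": 1},
            0,
            g6pd_cap,
            gpr="gG6PD",
        ),
        rxn(
            "PGD",
            "6-phosphogluconate dehydrogenase",
            {"p6g_c": -1, "nadp_c": -1, "ru5p_c": 1, "nadph_c": 1, "co2_c": 1},
            0,
            pgd_cap,
            gpr="gPGD",
        ),
        rxn("EX_p6g", "6-phosphogluconate export", {"p6g_c": -1}, 0, BIG, exchange=True),
        rxn("NONOX", "non-oxidative PPP (lumped)", {"ru5p_c": -1, "pyr_c": 1}, 0, BIG),
        rxn("PC", "pyruvate carboxylase", {"pyr_c": -1, "co2_c": -1, "oaa_c": 1}, 0, BIG, gpr="gPC"),
        rxn(
            "CS",
            "citrate synthase (lumped with PDH)",
            {"pyr_c": -1, "oaa_c": -1, "cit_c": 1, "co2_c": 1},
            0,
            cfg.tca_cap,
            gpr="gCS",
        ),
        rxn(
            "ACLY",
            "ATP-citrate lyase",
            {"cit_c": -1, "accoa_c": 1, "oaa_c": 1},
            0,
            cfg.acly_cap,
            gpr="gACLY1 and gACLY2",
        ),
        rxn("MDH", "malate dehydrogenase", {"oaa_c": -1, "mal_c": 1}, -BIG, BIG, gpr="gMDH"),
        rxn(
            "ME",
            "malic enzyme",
            {"mal_c": -1, "nadp_c": -1, "pyr_c": 1, "co2_c": 1, "nadph_c": 1},
            0,
            me_cap,
            gpr="gME",
        ),
        rxn(
            "FAS",
            "fatty acid synthesis (lumped)",
            {"accoa_c": -1, "nadph_c": -k, "aa_c": 1, "nadp_c": k},
            0,
            cfg.fas_cap,
            gpr="gFAS1 and gFAS2",
        ),
        rxn("EX_aa", "arachidonic acid export", {"aa_c": -1}, 0, cfg.aa_export_cap, exchange=True),
        rxn("TCA", "TCA cycle (lumped, energy)", {"accoa_c": -1, "co2_c": 2}, 0, BIG, gpr="gTCA"),
        rxn("EX_co2", "CO2 exchange", {"co2_c": -1}, 0, BIG, exchange=True),
        rxn("NH4t", "ammonium transport", {"nh4_e": -1, "nh4_c": 1}, 0, BIG),
        rxn("EX_nh4", "ammonium exchange", {"nh4_e": -1}, -cfg.ammonium_uptake, BIG, exchange=True),
        rxn(
            "BIOMASS",
            "biomass drain",
            {
                "g6p_c": -_BIOMASS_G6P,
                "pyr_c": -_BIOMASS_PYR,
                "accoa_c": -_BIOMASS_ACCOA,
                "nh4_c": -_BIOMASS_NH4,
            },
            0,
            cfg.biomass_cap,
        ),
        rxn("NADPH_SINK", "non-lipogenic NADPH demand", {"nadph_c": -1, "nadp_c": 1}, 0, 0.5),
    ]

    genes = {
        "gHK1",
        "gGCK",
        "gGLYC",
        "gG6PD",
        "gPGD",
        "gPC",
        "gCS",
        "gACLY1",
        "gACLY2",
        "gMDH",
        "gME",
        "gFAS1",
        "gFAS2",
        "gTCA",
    }
    return MetabolicModel(
        id="toy_core_network",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        default_objective="EX_aa",
    )


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Planted-signal FPKM simulation parameters.

    ``effect`` is the post/pre fold planted for up genes (inverse for down
    genes); ``sigma`` the standard deviation of the natural-log
    multiplicative noise; ``n_background`` flat genes are added around the
    planted table.  Identical seeds give identical matrices.
    """

    regulation: RegulationTable
    effect: float = 8.0
    n_background: int = 500
    sigma: float = 0.2
    seed: int = 0
    baseline_log10_mean: float = 1.5  # ~30 FPKM typical baseline
    baseline_log10_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.effect <= 1:
            raise ValidationError(f"effect size must be > 1, got {self.effect}")
        if self.sigma < 0:
            raise ValidationError(f"sigma must be ≥ 0, got {self.sigma}")
        if self.n_background < 0:
            raise ValidationError("n_background must be ≥ 0")


def simulate_expression(config: ExpressionSimConfig) -> ExpressionMatrix:
    """Simulate a six-sample FPKM matrix with the configured planted signal.

    Planted up genes have post-phase mean = effect × pre-phase mean, down
    genes the inverse, unchanged/background genes are flat; every entry
    then receives independent multiplicative log-normal noise exp(σ·z).
    """
    rng = np.random.default_rng(config.seed)
    labels = list(STANDARD_SAMPLES)
    phases = {s: STANDARD_SAMPLES[s][0] for s in labels}
    times = {s: STANDARD_SAMPLES[s][1] for s in labels}

    genes = list(config.regulation.directions)
    genes += [f"BG{i:04d}" for i in range(config.n_background)]
    directions = dict(config.regulation.directions)

    baselines = 10.0 ** rng.normal(
        config.baseline_log10_mean, config.baseline_log10_sd, size=len(genes)
    )
    rows = []
    for gene, base in zip(genes, baselines):
        direction = directions.get(gene, "unchanged")
        post_mean = base * {
            "up": config.effect,
            "down": 1.0 / config.effect,
            "unchanged": 1.0,
        }[direction]
        means = [base if phases[s] == "pre" else post_mean for s in labels]
        noise = np.exp(config.sigma * rng.standard_normal(len(labels)))
        rows.append(np.asarray(means) * noise)
    values = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=labels)
    return ExpressionMatrix(values=values, phases=phases, times=times)


def perturb_regulation(table: RegulationTable, flips: int, seed: int = 0) -> RegulationTable:
    """Flip *flips* randomly chosen entries to a different direction.

    Deterministic per seed.  Useful to build concordance cases, e.g. one
    flip on the 23-gene core → concordance 22/23.
    """
    if flips > len(table):
        raise ValidationError(f"cannot flip {flips} of {len(table)} entries")
    rng = np.random.default_rng(seed)
    genes = list(table.directions)
    chosen = rng.choice(len(genes), size=flips, replace=False)
    directions = dict(table.directions)
    for idx in chosen:
        gene = genes[idx]
        alternatives = [d for d in DIRECTIONS if d != directions[gene]]
        directions[gene] = alternatives[rng.integers(len(alternatives))]
    return RegulationTable(
        directions=directions, enzymes=dict(table.enzymes), pathways=dict(table.pathways)
    )
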