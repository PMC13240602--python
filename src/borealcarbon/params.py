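"""Plant-functional-type and disturbance parameterization.

The live-carbon parameterization follows a boreal/temperate forest PFT:
GPP saturates with stand age on a recovery timescale tau_rec, responds
log-linearly to atmospheric CO2 with an empirical downregulation factor
gamma (progressive nutrient limitation), and exponentially to the air
temperature anomaly; respiration follows Q10 kinetics. The carboxylation
scaling (vcmax_scale = 1.11) and the across-the-board respiration reduction
(respiration_scale = 0.75) are calibration multipliers applied on top of
the base rates, and gamma defaults to 0.5.

Fire carbon partitioning is tissue- and PFT-class-specific: each burned
tissue splits into a combusted (CO2) fraction, a litter fraction, and a
small retained-live residual that implicitly represents standing dead
trees surviving the burn. Harvest routes stem wood into short- and
long-lived product pools and all other killed tissue to litter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .pools import CarbonPools

#: Leaf-habit classes resolvable in the fire partition table.
PFT_CLASSES = ("needleleaf", "broadleaf", "nonwoody")


@dataclass(frozen=True)
class PftParams:
    """Parameters for one plant functional type.

    Rates are per year; carbon densities kg C m^-2; temperatures degC.
    """

    woody: bool = True
    leaf_habit: str = "needleleaf"  # needleleaf | broadleaf | nonwoody

    # productivity
    gpp_max: float = 0.9  # kg C m^-2 yr^-1, mature-stand ceiling before scalings
    vcmax_scale: float = 1.11  # carboxylation-capacity multiplier on GPP
    tau_rec: float = 18.0  # yr; age-recovery timescale, plateau ~50 yr
    beta_gpp: float = 0.02  # degC^-1, GPP climate sensitivity
    gamma: float = 0.5  # unitless CO2 downregulation
    c0_ppm: float = 277.0  # reference CO2 (spin-up year concentration)

    # respiration
    q10: float = 2.0
    respiration_scale: float = 0.75  # multiplier on all respiration rates
    growth_resp_frac: float = 0.25  # fraction of GPP before scaling
    resp_rate_green_leaf: float = 0.25  # yr^-1 maintenance, per unit pool
    resp_rate_stem: float = 0.015
    resp_rate_root: float = 0.12

    # allocation of allocatable assimilate (sums to 1)
    alloc_leaf: float = 0.35
    alloc_stem: float = 0.35
    alloc_root: float = 0.30

    # tissue turnover times (yr)
    tau_green_leaf: float = 3.0  # green leaf -> brown (standing dead) leaf
    tau_brown_leaf: float = 1.0  # brown leaf -> litter
    tau_stem: float = 45.0
    tau_root: float = 10.0

    # decomposition
    k_litter: float = 0.15  # yr^-1 at reference temperature
    k_soil: float = 0.02
    humification_frac: float = 0.30  # litter decay routed to soil

    def __post_init__(self) -> None:
        if self.leaf_habit not in PFT_CLASSES:
            raise ValueError(f"unknown leaf_habit {self.leaf_habit!r}")
        alloc = self.alloc_leaf + self.alloc_stem + self.alloc_root
        if abs(alloc - 1.0) > 1e-12:
            raise ValueError(f"allocation fractions must sum to 1, got {alloc}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.gpp_max < 0:
            raise ValueError("gpp_max must be >= 0")
        for name in (
            "vcmax_scale", "tau_rec", "q10", "respiration_scale",
            "resp_rate_green_leaf", "resp_rate_stem", "resp_rate_root",
            "tau_green_leaf", "tau_brown_leaf", "tau_stem", "tau_root",
            "k_litter", "k_soil", "c0_ppm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # Annual explicit update: per-pool loss rates (maintenance + turnover,
        # at a generous Q10 excursion) must stay below 1 to keep pools >= 0.
        hot = self.q10 ** 0.5  # +5 degC anomaly head-room
        checks = {
            "green_leaf": self.respiration_scale * self.resp_rate_green_leaf * hot
            + 1.0 / self.tau_green_leaf,
            "brown_leaf": 1.0 / self.tau_brown_leaf,
            "stem": self.respiration_scale * self.resp_rate_stem * hot
            + 1.0 / self.tau_stem,
            "root": self.respiration_scale * self.resp_rate_root * hot
            + 1.0 / self.tau_root,
            "litter": self.k_litter * hot,
            "soil": self.k_soil * hot,
        }
        for pool, rate in checks.items():
            if rate > 1.0:
                raise ValueError(
                    f"annual loss rate for {pool} is {rate:.3f} > 1; "
                    "reduce rates or turnover speeds"
                )

    def with_(self, **kwargs) -> "PftParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TissueFire:
    """Fire fate of one tissue: combusted + litter <= 1, remainder survives."""

    frac_to_co2: float
    frac_to_litter: float

    def __post_init__(self) -> None:
        for v in (self.frac_to_co2, self.frac_to_litter):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fire fractions must lie in [0, 1]")
        if self.frac_to_co2 + self.frac_to_litter > 1.0 + 1e-12:
            raise ValueError(
                "frac_to_co2 + frac_to_litter must not exceed 1 "
                f"({self.frac_to_co2} + {self.frac_to_litter})"
            )

    @property
    def frac_retained(self) -> float:
        return max(0.0, 1.0 - self.frac_to_co2 - self.frac_to_litter)


@dataclass(frozen=True)
class FirePartitionTable:
    """Stand-replacing fire carbon partitioning, per tissue x PFT class.

    The retained residuals (e.g., 1% of green leaf) carry over as live
    carbon on the new age-0 tile, standing in for fire-surviving and
    standing-dead structure.
    """

    green_leaf_woody: TissueFire = field(
        default_factory=lambda: TissueFire(0.67, 0.32))
    green_leaf_nonwoody: TissueFire = field(
        default_factory=lambda: TissueFire(0.82, 0.17))
    brown_leaf: TissueFire = field(
        default_factory=lambda: TissueFire(0.90, 0.09))
    stem_needleleaf: TissueFire = field(
        default_factory=lambda: TissueFire(0.165, 0.83))
    stem_broadleaf: TissueFire = field(
        default_factory=lambda: TissueFire(0.125, 0.87))
    root: TissueFire = field(default_factory=lambda: TissueFire(0.0, 1.0))
    litter_combust_frac: float = 0.10
    soil_combust_frac: float = 0.02

    def __post_init__(self) -> None:
        for v in (self.litter_combust_frac, self.soil_combust_frac):
            if not 0.0 <= v <= 1.0:
                raise ValueError("combustion fractions must lie in [0, 1]")

    def green_leaf(self, pft_class: str) -> TissueFire:
        self._check(pft_class)
        return (self.green_leaf_nonwoody if pft_class == "nonwoody"
                else self.green_leaf_woody)

    def stem(self, pft_class: str) -> TissueFire:
        self._check(pft_class)
        if pft_class == "broadleaf":
            return self.stem_broadleaf
        # nonwoody PFTs carry ~no stem; needleleaf fractions are the default
        return self.stem_needleleaf

    @staticmethod
    def _check(pft_class: str) -> None:
        if pft_class not in PFT_CLASSES:
            raise KeyError(f"unknown PFT class {pft_class!r}")

    def as_dict(self) -> dict[str, float]:
        return {
            "green_leaf_woody_to_co2": self.green_leaf_woody.frac_to_co2,
            "green_leaf_woody_to_litter": self.green_leaf_woody.frac_to_litter,
            "green_leaf_nonwoody_to_co2": self.green_leaf_nonwoody.frac_to_co2,
            "green_leaf_nonwoody_to_litter": self.green_leaf_nonwoody.frac_to_litter,
            "brown_leaf_to_co2": self.brown_leaf.frac_to_co2,
            "brown_leaf_to_litter": self.brown_leaf.frac_to_litter,
            "stem_needleleaf_to_co2": self.stem_needleleaf.frac_to_co2,
            "stem_needleleaf_to_litter": self.stem_needleleaf.frac_to_litter,
            "stem_broadleaf_to_co2": self.stem_broadleaf.frac_to_co2,
            "stem_broadleaf_to_litter": self.stem_broadleaf.frac_to_litter,
            "root_to_co2": self.root.frac_to_co2,
            "root_to_litter": self.root.frac_to_litter,
            "litter_combust_frac": self.litter_combust_frac,
            "soil_combust_frac": self.soil_combust_frac,
        }


@dataclass(frozen=True)
class HarvestParams:
    """Wood-harvest partitioning and product-pool decay.

    Removed stem wood splits between a short-lived (paper/fuel, ~5 yr) and a
    long-lived (lumber, ~50 yr) product pool; logging residue (the rest of
    the stem plus all leaf and root mass) enters litter. Product decay is a
    first-order atmospheric source. These values are calibration defaults,
    exposed in configuration.
    """

    stem_removed_frac: float = 0.85
    product_short_frac: float = 0.40  # of the removed stem
    product_long_frac: float = 0.60
    decay_rate_short: float = 1.0 / 5.0  # yr^-1
    decay_rate_long: float = 1.0 / 50.0

    def __post_init__(self) -> None:
        for name in ("stem_removed_frac", "product_short_frac",
                     "product_long_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.product_short_frac + self.product_long_frac - 1.0) > 1e-12:
            raise ValueError("product split fractions must sum to 1")
        if self.decay_rate_short < 0 or self.decay_rate_long < 0:
            raise ValueError("product decay rates must be >= 0")


def default_initial_pools() -> CarbonPools:
    """Bare-ground initial state used to start spin-up."""
    return CarbonPools(green_leaf=0.01, brown_leaf=0.0, stem=0.01,
                       root=0.01, litter=0.1, soil=1.0)
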