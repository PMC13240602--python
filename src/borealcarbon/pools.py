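"""Carbon pool state for a single tile.

All masses are carbon areal densities in kg C m^-2. The live compartments
(green leaf, brown/standing-dead leaf, stem, root) feed litter through
turnover; litter humifies partly into soil; harvested stem wood enters two
wood-product pools with distinct residence times.
"""

from __future__ import annotations

FIELDS = (
    "green_leaf",
    "brown_leaf",
    "stem",
    "root",
    "litter",
    "soil",
    "products_short",
    "products_long",
)

LIVE_FIELDS = ("green_leaf", "brown_leaf", "stem", "root")


class CarbonPools:
    """Per-tile carbon masses by compartment (kg C m^-2).

    Invariants: every compartment is non-negative; the above-ground biomass
    diagnostic is green_leaf + brown_leaf + stem (roots excluded).
    """

    __slots__ = FIELDS

    def __init__(
        self,
        green_leaf: float = 0.0,
        brown_leaf: float = 0.0,
        stem: float = 0.0,
        root: float = 0.0,
        litter: float = 0.0,
        soil: float = 0.0,
        products_short: float = 0.0,
        products_long: float = 0.0,
    ) -> None:
        self.green_leaf = green_leaf
        self.brown_leaf = brown_leaf
        self.stem = stem
        self.root = root
        self.litter = litter
        self.soil = soil
        self.products_short = products_short
        self.products_long = products_long
        self.validate()

    def validate(self) -> None:
        for name in FIELDS:
            v = getattr(self, name)
            if not (v >= 0.0):  # catches NaN too
                raise ValueError(f"carbon pool {name!r} must be >= 0, got {v}")

    def total(self) -> float:
        """Total carbon including wood products, kg C m^-2."""
        return (
            self.green_leaf
            + self.brown_leaf
            + self.stem
            + self.root
            + self.litter
            + self.soil
            + self.products_short
            + self.products_long
        )

    def agb(self) -> float:
        """Above-ground biomass carbon: leaves + stem, roots excluded."""
        return self.green_leaf + self.brown_leaf + self.stem

    def copy(self) -> "CarbonPools":
        return CarbonPools(*(getattr(self, f) for f in FIELDS))

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FIELDS}

    def scaled(self, factor: float) -> "CarbonPools":
        """Return pools multiplied by a non-negative scalar."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return CarbonPools(*(getattr(self, f) * factor for f in FIELDS))

    def __add__(self, other: "CarbonPools") -> "CarbonPools":
        return CarbonPools(
            *(getattr(self, f) + getattr(other, f) for f in FIELDS)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        body = ", ".join(f"{f}={getattr(self, f):.4g}" for f in FIELDS)
        return f"CarbonPools({body})"
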