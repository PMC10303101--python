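"""Hair-element panel schema: the 31-element ICP-MS mineralogram.

Each element carries its hair reference interval (μg/g) and a class label:
``toxic`` elements have upper-limit-only reference intervals ("< x μg/g"),
``essential`` elements usually have a two-sided interval. The panel and the
intervals are the ones used by commercial hair mineralogram reports for
non-occupationally exposed adults.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Element",
    "ElementSchema",
    "default_element_schema",
    "TOXIC_SYMBOLS",
    "ESSENTIAL_SYMBOLS",
]


@dataclass(frozen=True)
class Element:
    """One panel element with its hair reference interval in μg/g."""

    symbol: str
    name: str
    element_class: str  # "toxic" | "essential"
    reference_lower: float | None  # None for upper-limit-only intervals
    reference_upper: float

    def __post_init__(self) -> None:
        if self.element_class not in ("toxic", "essential"):
            raise ValueError(f"unknown element class {self.element_class!r}")
        if self.element_class == "toxic" and self.reference_lower is not None:
            raise ValueError(
                f"toxic element {self.symbol} must have an upper-limit-only interval"
            )
        if self.reference_upper <= 0:
            raise ValueError(f"{self.symbol}: reference_upper must be > 0")
        if self.reference_lower is not None and not (
            0 <= self.reference_lower < self.reference_upper
        ):
            raise ValueError(f"{self.symbol}: invalid reference interval")


# (symbol, name, class, ref_lower, ref_upper) — hair reference intervals, μg/g.
_PANEL: tuple[tuple[str, str, str, float | None, float], ...] = (
    # toxic metals: upper-limit-only intervals
    ("Al", "Aluminium", "toxic", None, 8.0),
    ("Sb", "Antimony", "toxic", None, 0.066),
    ("As", "Arsenic", "toxic", None, 0.080),
    ("Ba", "Barium", "toxic", None, 0.75),
    ("Bi", "Bismuth", "toxic", None, 2.0),
    ("Cd", "Cadmium", "toxic", None, 0.070),
    ("Pb", "Lead", "toxic", None, 1.0),
    ("Hg", "Mercury", "toxic", None, 0.40),
    ("U", "Uranium", "toxic", None, 0.060),
    ("Ni", "Nickel", "toxic", None, 0.20),
    ("Ag", "Silver", "toxic", None, 0.14),
    ("Sn", "Tin", "toxic", None, 0.30),
    ("Ti", "Titanium", "toxic", None, 0.70),
    # essential and other elements
    ("Cu", "Copper", "essential", 11.0, 32.0),
    ("Zn", "Zinc", "essential", 110.0, 190.0),
    ("Mn", "Manganese", "essential", 0.08, 0.50),
    ("Cr", "Chromium", "essential", 0.40, 0.70),
    ("V", "Vanadium", "essential", 0.025, 0.10),
    ("Mo", "Molybdenum", "essential", 0.040, 0.090),
    ("B", "Boron", "essential", 0.50, 3.5),
    ("I", "Iodine", "essential", 0.25, 1.3),
    ("Li", "Lithium", "essential", 0.007, 0.020),
    ("Se", "Selenium", "essential", 0.70, 1.1),
    ("Sr", "Strontium", "essential", 0.21, 2.1),
    ("S", "Sulphur", "essential", 44000.0, 51000.0),
    ("Co", "Cobalt", "essential", 0.004, 0.020),
    ("Fe", "Iron", "essential", 7.0, 16.0),
    ("Ge", "Germanium", "essential", 0.030, 0.040),
    ("Rb", "Rubidium", "essential", 0.008, 0.080),
    ("Zr", "Zirconium", "essential", 0.060, 0.70),
    ("Au", "Gold", "essential", None, 0.50),  # reported as "< 0.50"
)


class ElementSchema:
    """Ordered collection of the 31 panel elements, keyed by symbol."""

    def __init__(self, elements: tuple[Element, ...]) -> None:
        self.elements = elements
        self._by_symbol = {e.symbol: e for e in elements}
        if len(self._by_symbol) != len(elements):
            raise ValueError("duplicate element symbols")

    def __len__(self) -> int:
        return len(self.elements)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def __getitem__(self, symbol: str) -> Element:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            near = ", ".join(
                s for s in self._by_symbol if s.lower().startswith(symbol[:1].lower())
            )
            raise KeyError(
                f"unknown element symbol {symbol!r}; nearest matches: {near or 'none'}"
            ) from None

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.elements]

    @property
    def toxic(self) -> list[Element]:
        return [e for e in self.elements if e.element_class == "toxic"]

    @property
    def essential(self) -> list[Element]:
        return [e for e in self.elements if e.element_class == "essential"]


def default_element_schema() -> ElementSchema:
    """The default 31-element panel (13 toxic, 18 essential)."""
    return ElementSchema(tuple(Element(*row) for row in _PANEL))


TOXIC_SYMBOLS: tuple[str, ...] = tuple(r[0] for r in _PANEL if r[2] == "toxic")
ESSENTIAL_SYMBOLS: tuple[str, ...] = tuple(r[0] for r in _PANEL if r[2] == "essential")
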