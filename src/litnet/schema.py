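"""The relationship-theme schema.

Themes are the semantic relationship classes identified from the four path
dendrograms — e.g. N (inhibits) for chemical-gene, Sa (side effect) for
chemical-disease, U (causal mutations) for gene-disease.  Each theme has a
symbol, a relationship type, and a direction flag: "reverse" themes (O, K,
Z, Mp, Md, X, L) describe the relationship read from the second entity to
the first but live under the same dendrogram, because paths are always
extracted in a fixed type orientation.  The A and E theme families carry
+/- sign variants whose member paths were separated manually.

The packaged schema contains 10 chemical-gene, 7 chemical-disease,
10 gene-disease and 9 gene-gene themes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

PAIR_TYPES = ("chemical-gene", "chemical-disease", "gene-disease", "gene-gene")


@dataclass(frozen=True)
class Theme:
    symbol: str
    relationship_type: str
    description: str
    direction: str = "forward"  # "forward" or "reverse"
    supporting_clusters: tuple[str, ...] = ()

    @property
    def sign(self) -> str:
        """'+', '-' or '' — the manual directionality tag, if any."""
        return self.symbol[-1] if self.symbol[-1] in "+-" else ""

    @property
    def family(self) -> str:
        """Symbol with the sign stripped (E+, E-, E share family 'E')."""
        return self.symbol.rstrip("+-")


@dataclass
class ThemeSchema:
    themes: list[Theme]

    def __post_init__(self):
        for ptype in PAIR_TYPES:
            symbols = [t.symbol for t in self.for_type(ptype)]
            if len(symbols) != len(set(symbols)):
                raise ValueError(f"duplicate theme symbols within {ptype}")
            if not symbols:
                raise ValueError(f"no themes for relationship type {ptype}")

    def for_type(self, relationship_type: str) -> list[Theme]:
        return [t for t in self.themes if t.relationship_type == relationship_type]

    def symbols(self, relationship_type: str) -> list[str]:
        return [t.symbol for t in self.for_type(relationship_type)]

    def get(self, relationship_type: str, symbol: str) -> Theme:
        for t in self.for_type(relationship_type):
            if t.symbol == symbol:
                return t
        raise KeyError(f"no theme {symbol!r} for type {relationship_type!r}")

    def counts(self) -> dict[str, int]:
        return {ptype: len(self.for_type(ptype)) for ptype in PAIR_TYPES}


def load_schema(source: str | Path | None = None) -> ThemeSchema:
    """Load the packaged theme schema, or a custom TSV with the same columns."""
    if source is None:
        text = (
            resources.files("litnet").joinpath("data/theme_schema.tsv").read_text("utf-8")
        )
    else:
        text = Path(source).read_text("utf-8")
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    expected = ["relationship_type", "symbol", "theme", "direction", "supporting_clusters"]
    if header != expected:
        raise ValueError(f"unexpected schema header {header}")
    themes = []
    for line in lines[1:]:
        ptype, symbol, desc, direction, clusters = line.split("\t")
        themes.append(
            Theme(symbol, ptype, desc, direction, tuple(clusters.split(",")) if clusters else ())
        )
    return ThemeSchema(themes)
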