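"""The packaged *Pisione* dataset: combined-analysis topology, 44-character
morphological matrix, character classes, terminal coordinates and a
demonstration trait table.

See ``data/FIXTURE_NOTES.txt`` for provenance and caveats (notably: the
continuous trait columns other than ``complexity`` are synthetic
stand-ins for demonstration only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .characters import (CharacterMatrix, CharacterMeta, read_character_meta,
                         read_occurrences, read_traits)
from .tree import Phylogeny, parse_newick

__all__ = ["FixtureData", "load_fixture", "PISIONE_PREFIX",
           "PISIONIDENS_PREFIX"]

PISIONE_PREFIX = "Pisione_"
PISIONIDENS_PREFIX = "Pisionidens_"


@dataclass(frozen=True)
class FixtureData:
    tree: Phylogeny
    matrix: CharacterMatrix
    meta: CharacterMeta
    traits: pd.DataFrame
    occurrences: pd.DataFrame

    @property
    def pisione_taxa(self) -> list[str]:
        return [t for t in self.matrix.taxa if t.startswith(PISIONE_PREFIX)]

    @property
    def pisionidens_taxa(self) -> list[str]:
        return [t for t in self.matrix.taxa if t.startswith(PISIONIDENS_PREFIX)]

    @property
    def ingroup_taxa(self) -> list[str]:
        return self.pisionidens_taxa + self.pisione_taxa


def _data_path(name: str):
    return resources.files("morphotrace.data").joinpath(name)


def load_fixture() -> FixtureData:
    """Load the packaged dataset and cross-validate its pieces."""
    tree = parse_newick(_data_path("tree_combined.nwk").read_text())
    with resources.as_file(_data_path("matrix_table.csv")) as p:
        matrix = CharacterMatrix.from_csv(p)
    with resources.as_file(_data_path("characters_meta.csv")) as p:
        meta = read_character_meta(p)
    with resources.as_file(_data_path("traits_synthetic.csv")) as p:
        traits = read_traits(p)
    with resources.as_file(_data_path("occurrences.csv")) as p:
        occurrences = read_occurrences(p)

    meta.validate_against(matrix)
    tips = set(tree.tip_labels)
    missing = set(matrix.taxa) - tips
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    extra = tips - set(matrix.taxa)
    if extra:
        raise ValueError(f"tree tips absent from matrix: {sorted(extra)}")
    return FixtureData(tree=tree, matrix=matrix, meta=meta, traits=traits,
                       occurrences=occurrences)
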