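"""A small column-oriented on-disk store of dated editions.

The store is a directory tree of plain text, one file per edition,
with dates carried in file names::

    <data_root>/
      ontology/go.<YYYY-MM-DD>.obo
      annotations/goa_<species>.<YYYY-MM-DD>.gaf
      sec_ac.txt            (optional secondary->primary accession map)
      corpus.gmt, dates.tsv (optional stability corpus)

Everything is diff-able and reproducible; loading propagates each
annotation edition against the ontology release closest before it.
"""

from __future__ import annotations

import datetime
import os
import re
from pathlib import Path

from gochron.annotations import (
    AccessionMapping,
    harmonize,
    match_ontology,
    parse_gaf,
    parse_secondary_mapping,
    propagate_edition,
)
from gochron.errors import ConfigurationError
from gochron.history import EditionSeries
from gochron.ontology import OntologyEdition, parse_obo

OBO_NAME = re.compile(r"^go\.(\d{4}-\d{2}-\d{2})\.obo$")
GAF_NAME = re.compile(r"^goa_(.+)\.(\d{4}-\d{2}-\d{2})\.gaf$")


class EditionStore:
    """Lazy-loading view over a data_root directory tree."""

    def __init__(self, data_root: str | os.PathLike):
        self.root = Path(data_root)
        if not self.root.is_dir():
            raise ConfigurationError(f"data root {self.root} does not exist")
        self.ontology_paths: dict[datetime.date, Path] = {}
        for path in sorted((self.root / "ontology").glob("*.obo")):
            match = OBO_NAME.match(path.name)
            if match:
                self.ontology_paths[datetime.date.fromisoformat(match.group(1))] = path
        self.annotation_paths: dict[str, dict[datetime.date, Path]] = {}
        for path in sorted((self.root / "annotations").glob("*.gaf")):
            match = GAF_NAME.match(path.name)
            if match:
                species, date = match.group(1), datetime.date.fromisoformat(match.group(2))
                self.annotation_paths.setdefault(species, {})[date] = path
        if not self.ontology_paths:
            raise ConfigurationError(f"no ontology editions under {self.root / 'ontology'}")
        mapping_path = self.root / "sec_ac.txt"
        if mapping_path.exists():
            with open(mapping_path) as handle:
                self.mapping = parse_secondary_mapping(handle)
        else:
            self.mapping = AccessionMapping(secondary_to_primary={})
        self._ontology_cache: dict[datetime.date, OntologyEdition] = {}
        self._series_cache: dict[str, EditionSeries] = {}

    @property
    def species(self) -> list[str]:
        return sorted(self.annotation_paths)

    def ontology_dates(self) -> list[datetime.date]:
        return sorted(self.ontology_paths)

    def ontology(self, date: datetime.date) -> OntologyEdition:
        if date not in self._ontology_cache:
            with open(self.ontology_paths[date]) as handle:
                self._ontology_cache[date] = parse_obo(handle, date)
        return self._ontology_cache[date]

    def series(self, species: str | None = None) -> EditionSeries:
        """Load, harmonize and propagate every edition of one species."""
        species = self._resolve_species(species)
        if species not in self._series_cache:
            editions = []
            for date, path in sorted(self.annotation_paths[species].items()):
                with open(path) as handle:
                    edition = parse_gaf(handle, species, date)
                edition = harmonize(edition, self.mapping)
                matched = match_ontology(date, self.ontology_dates())
                editions.append(propagate_edition(edition, self.ontology(matched)))
            self._series_cache[species] = EditionSeries(species=species, editions=tuple(editions))
        return self._series_cache[species]

    def _resolve_species(self, species: str | None) -> str:
        if species is not None:
            if species not in self.annotation_paths:
                raise ConfigurationError(
                    f"species {species!r} not in store (have: {', '.join(self.species) or 'none'})"
                )
            return species
        if len(self.annotation_paths) != 1:
            raise ConfigurationError(
                f"store holds {len(self.annotation_paths)} species; pass --species"
            )
        return next(iter(self.annotation_paths))


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text to path via a temporary file + rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
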