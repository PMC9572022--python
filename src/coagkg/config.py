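"""Editable configuration tables shipped as package data.

Every matching rule that a curator might want to adjust lives in a TSV under
``coagkg/data``: the heme synonym and formulation-blocklist tables, the
common-name/gene-symbol alias table used for crosstalk matching, and the GO
cellular-component-to-compartment mapping.  The loaders here read those
defaults; each consumer also accepts a custom table.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("coagkg") / "data" / name)


def _read_single_column(name: str) -> frozenset[str]:
    out = set()
    with open(data_path(name), encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line.casefold())
    return frozenset(out)


@lru_cache(maxsize=None)
def load_heme_synonyms() -> frozenset[str]:
    """Names curated to the canonical heme entity."""
    return _read_single_column("heme_synonyms.tsv")


@lru_cache(maxsize=None)
def load_heme_blocklist() -> frozenset[str]:
    """Therapeutic heme formulations excluded from curation."""
    return _read_single_column("heme_blocklist.tsv")


@lru_cache(maxsize=None)
def load_aliases() -> dict[str, str]:
    """Case-folded common name -> canonical identifier for overlap matching.

    Values that are upper-case are HGNC symbols; anything else is the
    canonical case-folded name of a non-protein entity.
    """
    out: dict[str, str] = {}
    with open(data_path("aliases.tsv"), encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("alias\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"aliases.tsv:{line_no}: expected alias<TAB>canonical")
            out[fields[0].strip().casefold()] = fields[1].strip()
    return out


@lru_cache(maxsize=None)
def load_cc_mapping():
    """The default GO CC -> compartment mapping as a CompartmentMapping."""
    from .localization import CompartmentMapping

    return CompartmentMapping.from_tsv(data_path("cc_map.tsv"))
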