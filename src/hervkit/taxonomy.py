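"""HERV repeat-model taxonomy.

RepeatMasker annotates LTR retroelements with separate models for the long
terminal repeat (e.g. ``LTR7``) and the internal retroviral genes
(e.g. ``HERVH-int``).  This module maps model names onto the HERV hierarchy
(superfamily -> family -> group/name), pairs LTR models with the internal
models they can be joined with during defragmentation, and collapses
redundant aliases to canonical group names.

Five superfamilies are recognised, following the Repbase class system for
endogenous retroviruses: ERV1 (gamma-retrovirus-like), ERVK
(beta-retrovirus-like), ERVL (spuma-related), ERVL-MaLR (mammalian apparent
LTR retrotransposons) and a catch-all ``Unclassified`` group for LTR-class
models without a recognised family.

A minimal taxonomy covering the 25 commonly analysed solo-LTR names and one
internal partner model per family ships as package data; users extend or
override it with their own TSV (same columns, keyed by repName).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

SUPERFAMILIES = ("ERV1", "ERVK", "ERVL", "ERVL-MaLR", "Unclassified")

#: rmsk repFamily strings that map directly onto a HERV superfamily.
_RMSK_FAMILY_TO_SUPERFAMILY = {
    "ERV1": "ERV1",
    "ERVK": "ERVK",
    "ERVL": "ERVL",
    "ERVL-MaLR": "ERVL-MaLR",
}

_INTERNAL_SUFFIXES = ("-int", "_I")


@dataclass(frozen=True)
class RepeatTaxon:
    """One repeat model: its role, canonical group/family and join partners."""

    rep_name: str
    role: str  # "ltr" | "internal"
    group: str
    family: str
    superfamily: str
    partners: frozenset = field(default_factory=frozenset)


def is_internal_name(rep_name: str) -> bool:
    """RepeatMasker naming convention: internal models end in -int or _I."""
    return rep_name.endswith(_INTERNAL_SUFFIXES)


def strip_internal_suffix(rep_name: str) -> str:
    for suf in _INTERNAL_SUFFIXES:
        if rep_name.endswith(suf):
            return rep_name[: -len(suf)]
    return rep_name


def classify_superfamily(rep_class: str, rep_family: str) -> str:
    """Map rmsk class/family strings to a superfamily. Total function."""
    if rep_family in _RMSK_FAMILY_TO_SUPERFAMILY:
        return _RMSK_FAMILY_TO_SUPERFAMILY[rep_family]
    return "Unclassified"


class Taxonomy:
    """Lookup table of :class:`RepeatTaxon` with rmsk-based fallback.

    Unknown names are synthesised on the fly: role from the -int/_I naming
    convention, group = name with the internal suffix stripped, family =
    group, superfamily = Unclassified.  This mirrors how unclassified
    LTR-class fragments are kept as their own one-member families.
    """

    def __init__(self, taxa: Iterable[RepeatTaxon]):
        self._taxa: dict[str, RepeatTaxon] = {}
        for t in taxa:
            existing = self._taxa.get(t.rep_name)
            if existing is not None and existing != t:
                raise ValueError(
                    f"conflicting taxonomy rows for repName {t.rep_name!r}"
                )
            self._taxa[t.rep_name] = t

    def __len__(self) -> int:
        return len(self._taxa)

    def __contains__(self, rep_name: str) -> bool:
        return rep_name in self._taxa

    def lookup(self, rep_name: str) -> RepeatTaxon:
        taxon = self._taxa.get(rep_name)
        if taxon is not None:
            return taxon
        group = strip_internal_suffix(rep_name)
        return RepeatTaxon(
            rep_name=rep_name,
            role="internal" if is_internal_name(rep_name) else "ltr",
            group=group,
            family=group,
            superfamily="Unclassified",
        )

    def role_of(self, rep_name: str) -> str:
        return self.lookup(rep_name).role

    def family_of(self, rep_name: str) -> str:
        return self.lookup(rep_name).family

    def superfamily_of(self, rep_name: str) -> str:
        return self.lookup(rep_name).superfamily

    def canonical_group(self, rep_name: str) -> str:
        """Collapse aliases/internal suffixes to one canonical group string.

        Idempotent; names absent from the table map to themselves minus any
        internal-model suffix.
        """
        return self.lookup(rep_name).group

    def joinable(self, name_a: str, name_b: str) -> bool:
        """True iff two models may belong to the same element.

        Same canonical family, or an explicit LTR/internal partner link in
        either direction.  Symmetric by construction; reflexive on any name
        (family defaults to the name itself).
        """
        ta, tb = self.lookup(name_a), self.lookup(name_b)
        if ta.family == tb.family:
            return True
        return name_b in ta.partners or name_a in tb.partners

    def extended(self, taxa: Iterable[RepeatTaxon]) -> "Taxonomy":
        """New taxonomy with rows added/overridden by repName."""
        merged = dict(self._taxa)
        for t in taxa:
            merged[t.rep_name] = t
        return Taxonomy(merged.values())


def _parse_taxonomy_tsv(text: str) -> list[RepeatTaxon]:
    taxa = []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        return taxa
    header = lines[0].rstrip("\n").split("\t")
    expected = ["repName", "role", "group", "family", "superfamily", "partners"]
    if header != expected:
        raise ValueError(f"taxonomy TSV header must be {expected}, got {header}")
    for ln in lines[1:]:
        cols = ln.rstrip("\n").split("\t")
        if len(cols) < 5:
            raise ValueError(f"malformed taxonomy row: {ln!r}")
        partners = cols[5] if len(cols) > 5 else ""
        role = cols[1]
        if role not in ("ltr", "internal"):
            raise ValueError(f"unknown role {role!r} for {cols[0]!r}")
        superfamily = cols[4]
        if superfamily not in SUPERFAMILIES:
            raise ValueError(f"unknown superfamily {superfamily!r} for {cols[0]!r}")
        taxa.append(
            RepeatTaxon(
                rep_name=cols[0],
                role=role,
                group=cols[2],
                family=cols[3],
                superfamily=superfamily,
                partners=frozenset(p for p in partners.split(",") if p),
            )
        )
    seen: dict[str, RepeatTaxon] = {}
    for t in taxa:
        if t.rep_name in seen and seen[t.rep_name] != t:
            raise ValueError(f"conflicting taxonomy rows for repName {t.rep_name!r}")
        seen[t.rep_name] = t
    return taxa


def _bundled_text() -> str:
    return (
        resources.files("hervkit").joinpath("data/taxonomy.tsv").read_text()
    )


def load_taxonomy(path=None) -> Taxonomy:
    """Load the bundled taxonomy, optionally extended/overridden by a TSV.

    Parameters
    ----------
    path : str, Path, file-like or None
        User TSV with the documented header.  Rows override bundled rows
        with the same repName.  ``None`` (or an empty file) returns the
        bundled default unchanged.
    """
    base = Taxonomy(_parse_taxonomy_tsv(_bundled_text()))
    if path is None:
        return base
    if hasattr(path, "read"):
        text = path.read()
    else:
        with io.open(path, "rt") as fh:
            text = fh.read()
    if not text.strip():
        return base
    return base.extended(_parse_taxonomy_tsv(text))


def canonical_group(rep_name: str, taxonomy: Taxonomy | None = None) -> str:
    """Module-level convenience wrapper around :meth:`Taxonomy.canonical_group`."""
    if taxonomy is None:
        taxonomy = load_taxonomy()
    return taxonomy.canonical_group(rep_name)


def joinable(name_a: str, name_b: str, taxonomy: Taxonomy | None = None) -> bool:
    if taxonomy is None:
        taxonomy = load_taxonomy()
    return taxonomy.joinable(name_a, name_b)
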