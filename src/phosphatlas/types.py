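"""Core domain types for phosphoproteome compendia.

The package models a compendium of condition-dependent phosphopeptide
quantifications (log2 fold changes versus a control), the kinase →
substrate-site annotations used to infer kinase activities, catalogs of
stable protein complexes, and flanking sequences for motif scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SiteID",
    "PhosphoCompendium",
    "KinaseSubstrateSets",
    "ComplexCatalog",
    "FlankTable",
    "COMPENDIUM_COLUMNS",
    "count_phosphosites",
]

_PHOSPHO_RESIDUES = frozenset("STY")

_SITE_TOKEN_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[STY])(?P<position>[1-9][0-9]*)$")


@dataclass(frozen=True, order=True)
class SiteID:
    """A phosphorylatable residue: protein accession + residue letter + 1-based position.

    The canonical string form is ``"PROT_S123"`` and round-trips through
    :meth:`parse` / :meth:`__str__`.
    """

    protein: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in _PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if not isinstance(self.position, int) or self.position < 1:
            raise ValueError(f"position must be a positive integer, got {self.position!r}")
        if not self.protein:
            raise ValueError("protein accession must be non-empty")

    def __str__(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}"

    @classmethod
    def parse(cls, token: str) -> "SiteID":
        m = _SITE_TOKEN_RE.match(token)
        if m is None:
            raise ValueError(f"not a valid site token: {token!r}")
        return cls(m.group("protein"), m.group("residue"), int(m.group("position")))


#: Required columns of the long-format compendium table, in canonical order.
COMPENDIUM_COLUMNS = [
    "study",
    "condition",
    "replicate",
    "replicate_kind",
    "protein",
    "residue",
    "position",
    "mod_key",
    "log2_ratio",
]

_REPLICATE_KINDS = frozenset({"technical", "biological"})


def count_phosphosites(mod_key: str) -> int:
    """Number of phosphosites in a modification key such as ``"PROT:S123+T127"``."""
    _, _, sites = mod_key.partition(":")
    if not sites:
        raise ValueError(f"malformed mod_key: {mod_key!r}")
    return sites.count("+") + 1


@dataclass
class PhosphoCompendium:
    """Long table of per-condition log2 phosphopeptide fold changes, grouped by study.

    ``records`` is a DataFrame with :data:`COMPENDIUM_COLUMNS`.  Missing
    values are encoded as absent rows, never as sentinel numbers.
    """

    records: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COMPENDIUM_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"compendium table is missing columns: {missing}")
        self.records = self.records[COMPENDIUM_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on the first violation."""
        rec = self.records
        vals = pd.to_numeric(rec["log2_ratio"], errors="coerce").to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("log2_ratio must be finite")
        bad_kind = set(rec["replicate_kind"].unique()) - _REPLICATE_KINDS
        if bad_kind:
            raise ValueError(f"unknown replicate_kind values: {sorted(bad_kind)}")
        if (rec["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        # a condition belongs to exactly one study
        per_cond = rec.groupby("condition")["study"].nunique()
        multi = per_cond[per_cond > 1]
        if len(multi):
            raise ValueError(f"conditions mapped to multiple studies: {list(multi.index)}")

    @property
    def site_tokens(self) -> pd.Series:
        """Canonical ``PROT_S123`` token per record."""
        rec = self.records
        return rec["protein"] + "_" + rec["residue"] + rec["position"].astype(str)

    def provenance(self) -> pd.Series:
        """Per-site count of distinct studies reporting the site."""
        tokens = self.site_tokens
        return self.records.assign(_site=tokens).groupby("_site")["study"].nunique()

    def conditions(self) -> list[str]:
        return sorted(self.records["condition"].unique())

    def copy_with(self, records: pd.DataFrame, **report_updates) -> "PhosphoCompendium":
        rep = dict(self.report)
        rep.update(report_updates)
        return PhosphoCompendium(records.reset_index(drop=True), rep)


@dataclass
class KinaseSubstrateSets:
    """Kinase → set of substrate :class:`SiteID`, with per-edge source tags."""

    sets: dict[str, set[SiteID]]
    sources: dict[tuple[str, SiteID], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [k for k, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"kinases with empty substrate sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def kinases(self) -> list[str]:
        return sorted(self.sets)

    def exclude_autophosphorylation(self) -> "KinaseSubstrateSets":
        """Drop edges whose substrate lies on the kinase's own protein.

        The kinase identifier is matched against the site's protein
        accession; kinases left without substrates are removed.
        """
        new_sets = {}
        for kinase, sites in self.sets.items():
            kept = {s for s in sites if s.protein != kinase}
            if kept:
                new_sets[kinase] = kept
        new_sources = {
            (k, s): tags
            for (k, s), tags in self.sources.items()
            if k in new_sets and s in new_sets[k]
        }
        return KinaseSubstrateSets(new_sets, new_sources)


@dataclass
class ComplexCatalog:
    """Complex id → set of subunit protein accessions."""

    complexes: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [c for c, subs in self.complexes.items() if not subs]
        if empty:
            raise ValueError(f"complexes with no subunits: {empty}")

    def __len__(self) -> int:
        return len(self.complexes)

    def deduplicate(self, jaccard_threshold: float = 0.9) -> "ComplexCatalog":
        """Keep one copy of homologous complexes.

        Exact subunit-set duplicates always collapse; additionally any pair
        with Jaccard similarity >= ``jaccard_threshold`` collapses to the
        larger complex (ties broken by complex id for determinism).
        """
        # exact duplicates first: keep the lexicographically first id
        by_subunits: dict[frozenset[str], str] = {}
        for cid in sorted(self.complexes):
            subs = self.complexes[cid]
            by_subunits.setdefault(subs, cid)
        kept = {cid: subs for subs, cid in by_subunits.items()}

        # near-duplicates: greedy collapse into the larger complex
        order = sorted(kept, key=lambda c: (-len(kept[c]), c))
        retained: list[str] = []
        for cid in order:
            subs = kept[cid]
            absorbed = False
            for other in retained:
                osubs = kept[other]
                jac = len(subs & osubs) / len(subs | osubs)
                if jac >= jaccard_threshold:
                    absorbed = True
                    break
            if not absorbed:
                retained.append(cid)
        complexes = {cid: kept[cid] for cid in sorted(retained)}
        names = {cid: self.names.get(cid, cid) for cid in complexes}
        return ComplexCatalog(complexes, names)


@dataclass
class FlankTable:
    """Site → flanking sequence of odd length 2w+1 centred on the phosphoacceptor.

    Termini are padded with ``'_'`` so all flanks share the same window.
    """

    flanks: dict[SiteID, str]

    def __post_init__(self) -> None:
        for site, flank in self.flanks.items():
            if len(flank) % 2 != 1:
                raise ValueError(f"flank for {site} has even length {len(flank)}")
            centre = flank[len(flank) // 2]
            if centre != site.residue:
                raise ValueError(
                    f"flank centre {centre!r} does not match residue of {site}"
                )

    def __len__(self) -> int:
        return len(self.flanks)

    @property
    def window(self) -> int:
        """Half-width w of the flank window."""
        any_flank = next(iter(self.flanks.values()))
        return len(any_flank) // 2
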