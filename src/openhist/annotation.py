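"""Mapping of accepted PSMs to modified histone sites, with variant
resolution, canonical prioritization, cross-variant deduplication and
novelty flagging against a curated catalog.

Histone variants are near-identical in sequence, so a modified peptide
usually maps to several of them (KSTGGKAPR fits every H3 variant).  Core
histone sites are reported on the canonical variant, the first compatible
entry of an ordered priority list.  Linker histones H1 have no reference
variant: sites are reported once per compatible variant but counted a
single time in all totals (records mapping to the same peptide-level site
share a ``site_key``).

Positions are 1-based on the mature protein (initiator methionine
removed), matching standard histone nomenclature (H3K9, H4K77, H1.2 K33).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from openhist.chemistry import BIOLOGICAL
from openhist.proteolysis import ProteinEntry
from openhist.search import PSM

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "ISOBARIC_CLASSES",
    "mod_class_label",
    "map_sites",
    "flag_novel",
    "summarize",
    "write_site_table",
    "H3_PRIORITY",
]

#: modification names indistinguishable by MS because of isobaric masses
#: are reported as one joint class
ISOBARIC_CLASSES: tuple[frozenset[str], ...] = (
    frozenset({"lactyl", "carboxyethyl"}),
)
_ISOBARIC_LABELS = {frozenset({"lactyl", "carboxyethyl"}): "Lact.|Carb"}

#: canonical-first ordering of the bundled H3 variants
H3_PRIORITY = ("P68431", "Q71DI3", "P84243")


def mod_class_label(
    name: str, isobaric_classes: Sequence[frozenset[str]] = ISOBARIC_CLASSES
) -> str:
    for group in isobaric_classes:
        if name in group:
            return _ISOBARIC_LABELS.get(frozenset(group), "|".join(sorted(group)))
    return name


@dataclass
class SiteRecord:
    """A variant-resolved modified residue."""

    reported_variant: str
    variants: tuple[str, ...]  # all compatible variant accessions
    residue: str
    position: int  # 1-based on the mature protein
    mod_name: str
    mod_class: str
    psm_count: int = 0
    novel: bool | None = None
    site_key: tuple = ()  # shared by records that are one site in totals


def _peptide_mappings(
    peptide: str, proteome: Sequence[ProteinEntry]
) -> list[tuple[str, int]]:
    """All (accession, 1-based start) exact placements of the peptide."""
    out = []
    for prot in proteome:
        if prot.is_decoy:
            continue
        start = prot.sequence.find(peptide)
        while start != -1:
            out.append((prot.accession, start + 1))
            start = prot.sequence.find(peptide, start + 1)
    return out


def map_sites(
    psms: Sequence[PSM],
    proteome: Sequence[ProteinEntry],
    canonical_priority: Sequence[str] | None = None,
    isobaric_classes: Sequence[frozenset[str]] = ISOBARIC_CLASSES,
) -> list[SiteRecord]:
    """Lift the biologically modified positions of accepted PSMs to
    protein sites across all compatible variants.

    With a ``canonical_priority`` list the site is reported once, on the
    first compatible variant in the list (remaining compatibles listed in
    ``variants``).  Without one (linker-histone mode) a record is emitted
    per compatible variant, all sharing a ``site_key`` so they count once
    in totals.
    """
    by_prot = {p.accession: p for p in proteome if not p.is_decoy}
    # collect support per (mapping set, peptide position, mod)
    sites: dict[tuple, dict] = {}
    for psm in psms:
        if psm.is_decoy:
            continue
        bio = [
            (pos, m)
            for pos, ms in psm.form.mods
            for m in ms
            if m.category == BIOLOGICAL and 1 <= pos <= len(psm.peptide)
        ]
        if not bio:
            continue
        mappings = _peptide_mappings(psm.peptide, proteome)
        if not mappings:
            logger.warning(
                "peptide %s of spectrum %s not found in the proteome; skipped",
                psm.peptide, psm.spectrum_id,
            )
            continue
        for pos, mod in bio:
            residue = psm.peptide[pos - 1]
            placements = []
            ok = True
            for acc, start in mappings:
                prot_pos = start + pos - 1
                prot = by_prot[acc]
                if not (1 <= prot_pos <= len(prot.sequence)):
                    logger.warning(
                        "position %d outside %s; record rejected", prot_pos, acc
                    )
                    ok = False
                    break
                if prot.sequence[prot_pos - 1] != residue:
                    logger.warning(
                        "residue mismatch at %s:%d; record rejected", acc, prot_pos
                    )
                    ok = False
                    break
                placements.append((acc, prot_pos))
            if not ok or not placements:
                continue
            cls = mod_class_label(mod.name, isobaric_classes)
            key = (frozenset(placements), cls)
            rec = sites.setdefault(
                key,
                {
                    "placements": sorted(placements),
                    "residue": residue,
                    "mod_name": mod.name,
                    "mod_class": cls,
                    "count": 0,
                },
            )
            rec["count"] += 1
    out: list[SiteRecord] = []
    for (placeset, cls), rec in sorted(
        sites.items(), key=lambda kv: (kv[1]["placements"], kv[1]["mod_class"])
    ):
        placements = rec["placements"]
        variants = tuple(acc for acc, _ in placements)
        site_key = (frozenset(placements), cls)
        if canonical_priority:
            ranked = [acc for acc in canonical_priority if acc in variants]
            reported = ranked[0] if ranked else variants[0]
            position = dict(placements)[reported]
            out.append(
                SiteRecord(
                    reported, variants, rec["residue"], position,
                    rec["mod_name"], cls, rec["count"], site_key=site_key,
                )
            )
        else:
            for acc, pos in placements:
                out.append(
                    SiteRecord(
                        acc, variants, rec["residue"], pos,
                        rec["mod_name"], cls, rec["count"], site_key=site_key,
                    )
                )
    return out


def flag_novel(
    sites: Sequence[SiteRecord],
    catalog: str | Path | pd.DataFrame,
    isobaric_classes: Sequence[frozenset[str]] = ISOBARIC_CLASSES,
) -> list[SiteRecord]:
    """Set the ``novel`` flag on each site by intersection with a curated
    catalog of known (variant, position, modification) triples, supplied
    as a 3-column tab-separated file or DataFrame.  Matching is
    isobaric-aware: catalog entries are reduced to the same joint classes
    as the sites (lactyl and carboxyethyl are one indistinguishable
    class).  Malformed catalog rows are skipped with a warning."""
    if not isinstance(catalog, pd.DataFrame):
        catalog = pd.read_csv(
            catalog, sep="\t", header=None, names=["variant", "position", "mod"],
            comment="#", skip_blank_lines=True, dtype=str,
        )
    known: set[tuple[str, int, str]] = set()
    for _, row in catalog.iterrows():
        try:
            known.add(
                (
                    str(row.iloc[0]).strip(),
                    int(row.iloc[1]),
                    mod_class_label(str(row.iloc[2]).strip(), isobaric_classes),
                )
            )
        except (TypeError, ValueError):
            logger.warning("malformed catalog row skipped: %s", list(row))
    for s in sites:
        s.novel = not any(
            (acc, pos, s.mod_class) in known
            for acc, pos in zip(s.variants, _positions_of(s))
        )
    return list(sites)


def _positions_of(site: SiteRecord) -> list[int]:
    # site_key carries every (variant, position) placement
    placements = dict(sorted(site.site_key[0])) if site.site_key else {
        site.reported_variant: site.position
    }
    return [placements[acc] for acc in site.variants]


def summarize(sites: Sequence[SiteRecord]) -> dict[str, pd.DataFrame]:
    """Count tables: marks per (variant × modification class) and per
    (class × novelty).  Records sharing a ``site_key`` count once in the
    class×novelty totals (the cross-variant deduplication rule) but are
    listed per variant in the variant table."""
    if not sites:
        empty = pd.DataFrame()
        return {"by_variant": empty, "by_class": empty}
    rows = [
        {
            "variant": s.reported_variant,
            "mod_class": s.mod_class,
            "novel": s.novel,
            "site_key": s.site_key or (s.reported_variant, s.position, s.mod_class),
        }
        for s in sites
    ]
    df = pd.DataFrame(rows)
    by_variant = (
        df.groupby(["variant", "mod_class"]).size().unstack(fill_value=0).sort_index()
    )
    dedup = df.drop_duplicates("site_key")
    by_class = (
        dedup.groupby(["mod_class", "novel"], dropna=False)
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    return {"by_variant": by_variant, "by_class": by_class}


def write_site_table(sites: Sequence[SiteRecord], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "variant": s.reported_variant,
                "all_variants": ";".join(s.variants),
                "residue": s.residue,
                "position": s.position,
                "modification": s.mod_name,
                "mod_class": s.mod_class,
                "psm_count": s.psm_count,
                "novel": s.novel,
            }
            for s in sites
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
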