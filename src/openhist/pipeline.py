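"""Four-step orchestration of the discovery workflow.

Step 1 — closed search against the full database for protein
identification; non-histone proteins are abundance-ranked by spectral
counting and the top N are kept alongside the histones in the search
database.  Step 2 — open search; delta-mass histogram bins covering at
least a configurable fraction of the nonzero-delta PSMs and annotatable
by the registry are promoted to the chemical offset set.  Step 3 —
detailed-mass-offset search with the biological offsets of interest plus
the promoted artifacts, under both cleavage rules when tryptic peptides
are enabled, followed by grouped target-decoy FDR and the quality
filters.  Step 4 — open-search re-adjudication of isobaric assignments,
then site-level annotation.

Every step logs its input/output counts to a JSON-lines audit trail and
can be re-run in isolation through the underlying module functions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from openhist import annotation as _annot
from openhist import validation as _valid
from openhist.chemistry import (
    BIOLOGICAL,
    CHEMICAL_ARTIFACT,
    DERIVATIZATION,
    Modification,
    Registry,
    default_registry,
)
from openhist.proteolysis import (
    DigestionRule,
    PeptidoForm,
    Protocol,
    ProteinEntry,
    add_decoys,
    apply_protocol,
    digest,
    enumerate_forms,
    is_histone,
    read_fasta,
)
from openhist.search import (
    PSM,
    SearchConfig,
    closed_search,
    delta_histogram,
    dmo_search,
    open_search,
    write_psm_table,
)
from openhist.spectra import Spectrum, read_mgf

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "rank_proteins",
    "build_candidates",
    "stepwise_dmo_counts",
]


@dataclass
class RunConfig:
    """Declarative configuration of a full run.

    ``spectra`` and ``database`` accept in-memory objects or file paths
    (MGF / FASTA).  ``top_n_proteins`` controls the histone-plus-top-N
    database option of step 1 (0 keeps histones only).
    """

    spectra: Sequence[Spectrum] | str | Path = ()
    database: Sequence[ProteinEntry] | str | Path = ()
    registry: Registry | None = None
    protocol: str = "PRO-PIC"
    bio_offset_names: Sequence[str] | None = None
    top_n_proteins: int = 100
    enable_open_step: bool = True
    enable_dmo_step: bool = True
    enable_adjudication: bool = True
    enable_tryptic: bool = True
    enable_artifact_promotion: bool = True
    artifact_promotion_frac: float = 0.01
    fdr: float = 0.01
    grouped_fdr: bool = True
    min_by_fraction: float = 0.5
    require_unique_localization: bool = True
    max_missed_cleavages: int = 1
    min_peptide_length: int = 6
    max_peptide_length: int = 30
    closed_config: SearchConfig = field(default_factory=SearchConfig.closed)
    open_config: SearchConfig = field(default_factory=SearchConfig.open)
    dmo_config: SearchConfig = field(default_factory=SearchConfig.dmo)
    canonical_priority: Sequence[str] | None = _annot.H3_PRIORITY
    catalog: str | Path | pd.DataFrame | None = None
    output_dir: str | Path | None = None
    seed: int = 0

    def resolve(self) -> tuple[list[Spectrum], list[ProteinEntry], Registry, Protocol]:
        spectra = (
            read_mgf(self.spectra)
            if isinstance(self.spectra, (str, Path))
            else list(self.spectra)
        )
        database = (
            read_fasta(self.database)
            if isinstance(self.database, (str, Path))
            else list(self.database)
        )
        if not spectra:
            raise ValueError("no spectra supplied")
        if not database:
            raise ValueError("no database supplied")
        registry = self.registry or default_registry()
        protocol = Protocol.preset(self.protocol, registry)
        return spectra, database, registry, protocol


@dataclass
class RunReport:
    steps: list[dict] = field(default_factory=list)
    ranked_proteins: list[tuple[str, int]] = field(default_factory=list)
    histogram: pd.DataFrame | None = None
    promoted_artifacts: list[str] = field(default_factory=list)
    fdr_result: _valid.FdrResult | None = None
    final_psms: list[PSM] = field(default_factory=list)
    sites: list[_annot.SiteRecord] = field(default_factory=list)
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)

    def log_step(self, name: str, **counts) -> None:
        self.steps.append({"step": name, **counts})
        logger.info("step %s: %s", name, counts)

    def step_counts(self) -> dict[str, dict]:
        return {s["step"]: {k: v for k, v in s.items() if k != "step"} for s in self.steps}


def _merge_duplicates(forms: Sequence[PeptidoForm]) -> list[PeptidoForm]:
    """Identical peptidoforms arising from several variants (the H3 tail
    peptides are shared by every H3 variant) are merged into one
    candidate carrying all protein placements, so they compete as one."""
    merged: dict[tuple, PeptidoForm] = {}
    for f in forms:
        key = (
            f.sequence,
            tuple((pos, tuple(m.name for m in ms)) for pos, ms in f.mods),
            f.is_decoy,
            f.is_entrapment,
        )
        if key in merged:
            old = merged[key]
            proteins = tuple(dict.fromkeys(old.proteins + f.proteins))
            merged[key] = PeptidoForm(
                old.sequence, old.mods, proteins, old.is_decoy, old.is_entrapment
            )
        else:
            merged[key] = f
    return list(merged.values())


def build_candidates(
    database: Sequence[ProteinEntry],
    registry: Registry,
    protocol: Protocol,
    max_missed_cleavages: int = 1,
    min_length: int = 6,
    max_length: int = 30,
    include_tryptic: bool = False,
    with_decoys: bool = True,
    variable_mods: Sequence[Modification] = (),
    max_var_mods: int = 1,
) -> list[PeptidoForm]:
    """Base candidate peptidoforms for searching.

    Derivatized proteins are digested under the ArgC-like rule and carry
    the protocol chemistry; entrapment-species proteins (not derivatized
    during preparation) are digested tryptically without chemistry.
    ``include_tryptic`` adds under-derivatized tryptic peptides of the
    derivatized proteins.  ``variable_mods`` (typically the chemical
    artifacts promoted by the open-search step) are enumerated onto every
    peptide, at most ``max_var_mods`` per candidate.  Decoys (reversed
    sequences) follow the exact same construction as targets, and
    identical forms shared between variants are merged.
    """
    argc = DigestionRule(frozenset("R"), max_missed_cleavages, min_length, max_length)
    tryp = DigestionRule(frozenset("KR"), max_missed_cleavages, min_length, max_length)
    entries = add_decoys(database) if with_decoys else list(database)
    none_proto = Protocol("none", None, None)

    def _expand(pep, proto, derivatized):
        if variable_mods:
            return enumerate_forms(
                pep, variable_mods, max_var_mods=max_var_mods,
                protocol=proto, derivatized=derivatized,
            )
        return [apply_protocol(pep, proto, {}, derivatized=derivatized)]

    forms: list[PeptidoForm] = []
    for prot in entries:
        if prot.is_entrapment:
            for pep in digest(prot, tryp):
                forms.extend(_expand(pep, none_proto, False))
            continue
        argc_seqs = set()
        for pep in digest(prot, argc):
            argc_seqs.add(pep.sequence)
            forms.extend(_expand(pep, protocol, True))
        if include_tryptic:
            for pep in digest(prot, tryp):
                if pep.sequence not in argc_seqs:
                    forms.extend(_expand(pep, protocol, False))
    return _merge_duplicates(forms)


def rank_proteins(
    closed_psms: Sequence[PSM],
    database: Sequence[ProteinEntry],
    fdr: float = 0.01,
) -> list[tuple[str, int]]:
    """Spectral-count abundance ranking of non-histone proteins from the
    closed-search PSMs, at the given (global) FDR.  Deterministic ties by
    accession order."""
    result = _valid.compute_fdr(list(closed_psms), grouped=False, fdr=fdr,
                                peptide_level=False)
    histone_accs = {e.accession for e in database if is_histone(e)}
    counts: dict[str, int] = {}
    for p in result.accepted:
        for acc, _, _ in p.form.proteins:
            if acc not in histone_accs:
                counts[acc] = counts.get(acc, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _promote_artifacts(
    histogram: pd.DataFrame,
    registry: Registry,
    n_nonzero: int,
    frac: float,
) -> list[Modification]:
    """Delta-mass bins covering >= ``frac`` of the nonzero-delta PSMs and
    annotatable as a single non-biological registry modification are
    promoted to the chemical offset set."""
    promoted: dict[str, Modification] = {}
    if n_nonzero == 0:
        return []
    for _, row in histogram.iterrows():
        if row["count"] < frac * n_nonzero:
            continue
        hits = registry.by_mass(row["mean_delta"], tol=0.01)
        for mod in hits:
            if mod.category in (CHEMICAL_ARTIFACT, DERIVATIZATION):
                promoted.setdefault(mod.name, mod)
                break
    return list(promoted.values())


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full four-step workflow and return its report.  With an
    ``output_dir`` the PSM table, site table, summaries and the JSON-lines
    audit log are persisted; a failing step leaves the partial outputs of
    the completed steps in place."""
    spectra, database, registry, protocol = config.resolve()
    report = RunReport()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    try:
        # ---- step 1: closed search, protein ranking, database choice ---
        full_candidates = build_candidates(
            database, registry, protocol,
            config.max_missed_cleavages, config.min_peptide_length,
            config.max_peptide_length, include_tryptic=config.enable_tryptic,
        )
        closed_psms = closed_search(spectra, full_candidates, config.closed_config)
        report.ranked_proteins = rank_proteins(closed_psms, database, config.fdr)
        keep_accs = {e.accession for e in database if is_histone(e)}
        keep_accs.update(
            acc for acc, _ in report.ranked_proteins[: config.top_n_proteins]
        )
        search_db = [e for e in database if e.accession in keep_accs]
        if not search_db:
            search_db = list(database)
        report.log_step(
            "closed", n_spectra=len(spectra), n_candidates=len(full_candidates),
            n_psms=len(closed_psms), n_proteins_kept=len(search_db),
        )
        if not (config.enable_open_step or config.enable_dmo_step):
            report.final_psms = closed_psms
            if out_dir:
                write_psm_table(closed_psms, out_dir / "psm.tsv")
                _write_log(report, out_dir)
            return report

        candidates = build_candidates(
            search_db, registry, protocol,
            config.max_missed_cleavages, config.min_peptide_length,
            config.max_peptide_length, include_tryptic=config.enable_tryptic,
        )

        # ---- step 2: open search, artifact discovery --------------------
        promoted: list[Modification] = []
        if config.enable_open_step:
            open_psms = open_search(spectra, candidates, config.open_config)
            n_nonzero = sum(1 for p in open_psms if abs(p.delta_mass) > 0.01)
            report.histogram = delta_histogram(
                open_psms, bin_width=0.01, registry=registry
            )
            if config.enable_artifact_promotion:
                promoted = _promote_artifacts(
                    report.histogram, registry, n_nonzero,
                    config.artifact_promotion_frac,
                )
            report.promoted_artifacts = [m.name for m in promoted]
            report.log_step(
                "open", n_psms=len(open_psms), n_nonzero_delta=n_nonzero,
                promoted=report.promoted_artifacts,
            )
            if out_dir and report.histogram is not None:
                report.histogram.to_csv(out_dir / "delta_histogram.tsv",
                                        sep="\t", index=False)

        # ---- step 3: DMO search + grouped FDR + filters -----------------
        # pyruvoyl is excluded from the default offset set: its mass is
        # isobaric with propionyl + the in-gel +13.9792 artifact, so it
        # cannot be claimed from in-gel data
        bio_names = (
            list(config.bio_offset_names)
            if config.bio_offset_names is not None
            else [m.name for m in registry.by_category(BIOLOGICAL)
                  if m.name != "pyruvoyl"]
        )
        offsets = [registry[n] for n in bio_names]
        if promoted:
            # discovered artifacts enter as variable modifications so they
            # can co-occur with a biological mass offset
            candidates = build_candidates(
                search_db, registry, protocol,
                config.max_missed_cleavages, config.min_peptide_length,
                config.max_peptide_length, include_tryptic=config.enable_tryptic,
                variable_mods=promoted, max_var_mods=1,
            )
        dmo_psms = dmo_search(spectra, candidates, config.dmo_config, offsets=offsets)
        fdr_result = _valid.compute_fdr(
            dmo_psms, grouped=config.grouped_fdr, fdr=config.fdr
        )
        report.fdr_result = fdr_result
        filtered = _valid.filter_psms(
            fdr_result.accepted,
            min_by_fraction=config.min_by_fraction,
            require_unique_localization=config.require_unique_localization,
        )
        report.log_step(
            "dmo", n_offsets=len(offsets), n_psms=len(dmo_psms),
            n_accepted=len(fdr_result.accepted), n_filtered=len(filtered),
        )

        # ---- step 4: isobaric adjudication + annotation -----------------
        if config.enable_adjudication:
            adjudicated = _valid.adjudicate_isobaric(
                filtered, spectra, registry, config.dmo_config
            )
            final = [p for p in adjudicated if p.verdict == "kept"]
            report.log_step(
                "adjudicate", n_in=len(filtered), n_kept=len(final),
                n_discarded=len(adjudicated) - len(final),
            )
        else:
            final = filtered
        report.final_psms = final

        report.sites = _annot.map_sites(
            final, search_db, canonical_priority=config.canonical_priority
        )
        if config.catalog is not None:
            _annot.flag_novel(report.sites, config.catalog)
        report.summaries = _annot.summarize(report.sites)
        report.log_step("annotate", n_sites=len(report.sites))
    finally:
        if out_dir:
            if report.final_psms:
                write_psm_table(report.final_psms, out_dir / "psm.tsv")
            if report.sites:
                _annot.write_site_table(report.sites, out_dir / "sites.tsv")
            for name, df in report.summaries.items():
                df.to_csv(out_dir / f"summary_{name}.tsv", sep="\t")
            _write_log(report, out_dir)
    return report


def _write_log(report: RunReport, out_dir: Path) -> None:
    with open(out_dir / "run_log.jsonl", "w") as fh:
        for step in report.steps:
            fh.write(json.dumps(step, default=str) + "\n")


def stepwise_dmo_counts(
    spectra: Sequence[Spectrum],
    database: Sequence[ProteinEntry],
    registry: Registry,
    protocol: Protocol,
    bio_offset_names: Sequence[str],
    artifact_offset_names: Sequence[str],
    config: SearchConfig | None = None,
    fdr: float = 0.01,
    min_by_fraction: float = 0.5,
    max_missed_cleavages: int = 1,
) -> dict[str, int]:
    """Accepted-identification counts of the sequential DMO optimization:
    biological offsets only, + chemical artifact offsets, + tryptic
    peptides.  Used to audit that each enrichment of the search space
    increases identifications."""
    config = config or SearchConfig.dmo()
    proto = protocol
    bio = [registry[n] for n in bio_offset_names]
    art = [registry[n] for n in artifact_offset_names]
    counts: dict[str, int] = {}
    for label, var_mods, tryptic in (
        ("base", (), False),
        ("+artifacts", art, False),
        ("+tryptic", art, True),
    ):
        candidates = build_candidates(
            database, registry, proto,
            max_missed_cleavages=max_missed_cleavages, include_tryptic=tryptic,
            variable_mods=var_mods, max_var_mods=1,
        )
        psms = dmo_search(spectra, candidates, config, offsets=bio)
        result = _valid.compute_fdr(psms, grouped=True, fdr=fdr)
        filtered = _valid.filter_psms(result.accepted, min_by_fraction, True)
        counts[label] = len(filtered)
    return counts
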