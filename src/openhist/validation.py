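"""Group-wise target-decoy FDR, quality filters, isobaric re-adjudication
of DMO identifications, and entrapment error estimation.

Spectra of unmodified, chemically modified and biologically modified
peptides have different score characteristics, so a single global
target-decoy threshold can concentrate false matches in one group.  FDR
is therefore computed separately within three groups: (1) unmodified
peptides, (2) peptides with chemical modifications only, (3) peptides
bearing at least one genuine biological modification.  For entrapment
*reporting* a two-category convention is used instead (modified = at
least one biological mark; everything else, including purely chemical
derivatization, counts as unmodified); both conventions are exposed.

The entrapment error rate is the fraction of biologically modified
histone PSMs whose spectra originate from the entrapment species (which
has no histones, so every such assignment is a known false match):
``100 × entrapment-origin / total``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from openhist.chemistry import (
    BIOLOGICAL,
    CHEMICAL_ARTIFACT,
    DERIVATIZATION,
    Modification,
    Registry,
    decompose_delta,
)
from openhist.proteolysis import PeptidoForm
from openhist.search import (
    PSM,
    SearchConfig,
    _expand_with_offset,
    match_satellites,
    score_match,
)
from openhist.spectra import Spectrum, theoretical_fragments

logger = logging.getLogger(__name__)

__all__ = [
    "GROUP_UNMODIFIED",
    "GROUP_CHEMICAL",
    "GROUP_BIOLOGICAL",
    "assign_group",
    "FdrResult",
    "compute_fdr",
    "filter_psms",
    "adjudicate_isobaric",
    "EntrapmentReport",
    "entrapment_analysis",
]

GROUP_UNMODIFIED = "unmodified"
GROUP_CHEMICAL = "chemical_only"
GROUP_BIOLOGICAL = "biological"


def assign_group(psm: PSM, convention: str = "strict3") -> str:
    """FDR group of a PSM from its modification categories.

    ``strict3``: biological if any biological mark; chemical_only if any
    chemical artifact or derivatization and no biological; unmodified
    otherwise.  ``folded2``: biological vs everything-else (the
    two-category entrapment-reporting convention, where derivatization-
    only peptides count as unmodified).
    """
    cats = psm.form.categories()
    if BIOLOGICAL in cats:
        return GROUP_BIOLOGICAL
    if convention == "folded2":
        return GROUP_UNMODIFIED
    if CHEMICAL_ARTIFACT in cats or DERIVATIZATION in cats:
        return GROUP_CHEMICAL
    return GROUP_UNMODIFIED


# ---------------------------------------------------------------------------
# target-decoy FDR
# ---------------------------------------------------------------------------


@dataclass
class FdrResult:
    fdr: float
    grouped: bool
    thresholds: dict[str, float]  # per-group score threshold at the FDR
    group_sizes: dict[str, int]
    accepted: list[PSM]

    def __len__(self) -> int:
        return len(self.accepted)


def _qvalues(scores: np.ndarray, decoy: np.ndarray) -> np.ndarray:
    """q-value per PSM: min over score thresholds t <= s of
    (#decoys >= t) / (#targets >= t), no +1 correction, monotone."""
    n = len(scores)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    # tied scores share one threshold: count at the end of the tie group
    last_idx = n - 1 - np.searchsorted(s_sorted[::-1], s_sorted, side="left")
    fdr = d_cum[last_idx] / np.maximum(t_cum[last_idx], 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q
    return out


def _form_key(psm: PSM) -> tuple:
    return (psm.peptide, psm.form.assigned_mods_str(), psm.is_decoy)


def compute_fdr(
    psms: Sequence[PSM],
    grouped: bool = True,
    fdr: float = 0.01,
    peptide_level: bool = True,
    convention: str = "strict3",
) -> FdrResult:
    """Target-decoy q-values within each group (or globally), acceptance
    at the requested FDR at PSM level and, optionally, at peptidoform
    level (computed on the best PSM per peptidoform).  Decoy PSMs are
    never accepted; they only calibrate the thresholds."""
    psms = list(psms)
    for p in psms:
        p.fdr_group = assign_group(p, convention)
    groups: dict[str, list[PSM]] = {}
    for p in psms:
        key = p.fdr_group if grouped else "all"
        groups.setdefault(key, []).append(p)
    thresholds: dict[str, float] = {}
    sizes: dict[str, int] = {}
    accepted: list[PSM] = []
    for gname, members in sorted(groups.items()):
        sizes[gname] = len(members)
        scores = np.array([p.score for p in members])
        decoy = np.array([p.is_decoy for p in members])
        if (~decoy).sum() == 0:
            logger.warning("FDR group %r has no target PSMs; skipped", gname)
            continue
        q = _qvalues(scores, decoy)
        for p, qi in zip(members, q):
            p.q_value = float(qi)
        pass_scores = scores[(q <= fdr)]
        thresholds[gname] = float(pass_scores.min()) if len(pass_scores) else float("inf")
        ok = {id(p) for p, qi in zip(members, q) if qi <= fdr and not p.is_decoy}
        if peptide_level:
            best: dict[tuple, PSM] = {}
            for p in members:
                k = _form_key(p)
                if k not in best or p.score > best[k].score:
                    best[k] = p
            reps = list(best.values())
            q_pep = _qvalues(
                np.array([p.score for p in reps]),
                np.array([p.is_decoy for p in reps]),
            )
            pep_pass = {
                _form_key(p) for p, qi in zip(reps, q_pep) if qi <= fdr
            }
            ok = {id(p) for p in members if id(p) in ok and _form_key(p) in pep_pass}
        accepted.extend(p for p in members if id(p) in ok)
    return FdrResult(fdr, grouped, thresholds, sizes, accepted)


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------


def filter_psms(
    psms: Sequence[PSM],
    min_by_fraction: float = 0.5,
    require_unique_localization: bool = True,
) -> list[PSM]:
    """Retain PSMs with at least ``min_by_fraction`` of the theoretical
    b+y ions matched and (optionally) every mass offset unambiguously
    localized at exactly one position.  Idempotent and order-preserving."""
    out = []
    for p in psms:
        if p.matched_fraction < min_by_fraction:
            continue
        if require_unique_localization and p.delta_mass != 0.0:
            if not p.localized or p.n_best_positions != 1:
                continue
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# isobaric adjudication
# ---------------------------------------------------------------------------


def _alternative_forms(
    form: PeptidoForm,
    offset_mod: Modification,
    offset_pos: int,
    combo: Sequence[Modification],
) -> list[PeptidoForm]:
    """All placements of an isobaric modification combination on the base
    peptide (the PSM's form with its offset modification removed)."""
    # strip the offset mod from its slot
    mm = {p: [m for m in ms] for p, ms in form.mods}
    mm[offset_pos] = [m for m in mm.get(offset_pos, ()) if m.name != offset_mod.name]
    base = PeptidoForm.build(form.sequence, mm, form.proteins, form.is_decoy, form.is_entrapment)
    forms = [base]
    for mod in combo:
        nxt = []
        for f in forms:
            for pos, aa in enumerate(f.sequence, start=1):
                if not mod.applies_to(aa):
                    continue
                g = _expand_with_offset(f, mod, pos)
                if g is not None:
                    nxt.append(g)
        forms = nxt
        if not forms:
            return []
    # the combination must remain isobaric with the original form
    return [f for f in forms if abs(f.neutral_mass - form.neutral_mass) <= 0.01]


def adjudicate_isobaric(
    dmo_psms: Sequence[PSM],
    spectra: Mapping[str, Spectrum] | Sequence[Spectrum],
    registry: Registry,
    config: SearchConfig | None = None,
    max_terms: int = 2,
    tol: float = 0.001,
    snr_multiplier: float = 3.0,
    min_satellites: int = 2,
    reassign: bool = False,
) -> list[PSM]:
    """Re-adjudicate DMO identifications against isobaric alternatives.

    For each PSM carrying a mass offset, every registry decomposition of
    the offset modification's mass is re-placed on the same base peptide
    and rescored against the spectrum.  An alternative defeats the DMO
    assignment only when it scores strictly higher AND each peak it
    additionally matches exceeds a signal-to-noise floor
    (``snr_multiplier`` × the median intensity of peaks unmatched by the
    original assignment) — low-intensity extra matches are treated as
    noise, not evidence.  When the offset modification declares
    diagnostic neutral losses, the presence of at least
    ``min_satellites`` satellite ions overrides: the DMO assignment is
    kept on that evidence alone.

    Verdicts: ``kept``, ``discarded``, or (with ``reassign=True``)
    ``reassigned`` with the winning alternative substituted.
    """
    config = config or SearchConfig.dmo()
    if not isinstance(spectra, Mapping):
        spectra = {s.id: s for s in spectra}
    out = []
    for psm in dmo_psms:
        if psm.offset_name is None or psm.offset_name not in registry:
            psm.verdict = "kept"
            out.append(psm)
            continue
        spectrum = spectra[psm.spectrum_id]
        offset_mod = registry[psm.offset_name]
        frags = theoretical_fragments(psm.form, config.fragment_charges)
        # diagnostic neutral-loss override
        if offset_mod.diagnostic_neutral_losses:
            n_sat = match_satellites(spectrum, frags, config.fragment_tol_ppm)
            if n_sat >= min_satellites:
                psm.verdict = "kept"
                out.append(psm)
                continue
        orig_score, orig_report = score_match(spectrum, frags, config.fragment_tol_ppm)
        orig_peaks = set(orig_report.matched_peaks.tolist())
        combos = decompose_delta(offset_mod.mass, registry, max_terms=max_terms, tol=tol)
        verdict = "kept"
        winner: tuple[float, PeptidoForm] | None = None
        for combo, _err in combos:
            names = sorted(m.name for m in combo)
            if names == [offset_mod.name]:
                continue
            for alt in _alternative_forms(psm.form, offset_mod, psm.offset_position, combo):
                alt_score, alt_report = score_match(
                    spectrum, theoretical_fragments(alt, config.fragment_charges),
                    config.fragment_tol_ppm,
                )
                if alt_score <= orig_score:
                    continue
                alt_peaks = set(alt_report.matched_peaks.tolist())
                extra = alt_peaks - orig_peaks
                if not extra:
                    continue
                # noise level estimated from peaks explained by neither
                # assignment; the extra matches must stand clear of it
                residual = np.setdiff1d(
                    np.arange(len(spectrum.mz)), list(orig_peaks | alt_peaks)
                )
                floor = (
                    snr_multiplier * float(np.median(spectrum.intensity[residual]))
                    if len(residual)
                    else 0.0
                )
                if all(spectrum.intensity[i] >= floor for i in extra):
                    if winner is None or alt_score > winner[0]:
                        winner = (alt_score, alt)
        if winner is not None:
            if reassign:
                verdict = "reassigned"
                psm.form = winner[1]
                psm.score = winner[0]
            else:
                verdict = "discarded"
        psm.verdict = verdict
        out.append(psm)
    return out


# ---------------------------------------------------------------------------
# entrapment analysis
# ---------------------------------------------------------------------------


@dataclass
class EntrapmentReport:
    """Two-species entrapment error estimate.

    ``error_rate_pct`` = 100 × (entrapment-origin spectra assigned to
    biologically modified histone peptides) / (all spectra assigned to
    biologically modified histone peptides); None when the denominator is
    zero.
    """

    total_modified: int
    entrapment_modified: int
    breakdown: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def error_rate_pct(self) -> float | None:
        if self.total_modified == 0:
            return None
        return 100.0 * self.entrapment_modified / self.total_modified

    def to_text(self) -> str:
        lines = [
            "Entrapment analysis",
            f"  histone-modified PSMs (total):      {self.total_modified}",
            f"  of entrapment-species origin:       {self.entrapment_modified}",
        ]
        rate = self.error_rate_pct
        lines.append(
            f"  error rate:                         "
            + (f"{rate:.2f}%" if rate is not None else "undefined (no modified PSMs)")
        )
        for origin, counts in sorted(self.breakdown.items()):
            lines.append(
                f"  {origin}: modified={counts.get('modified', 0)} "
                f"unmodified={counts.get('unmodified', 0)}"
            )
        return "\n".join(lines)


def entrapment_analysis(
    psms: Sequence[PSM],
    histone_accessions: set[str] | Callable[[str], bool] | None = None,
) -> EntrapmentReport:
    """Entrapment error estimate from a combined two-species search.

    Spectra must carry their species of origin (``spectrum_species``;
    ``"entrapment"`` marks the foreign species).  ``histone_accessions``
    restricts which assigned proteins count as histones; by default every
    non-decoy, non-entrapment database protein does (true for
    histone-only databases).  The modified/unmodified breakdown uses the
    two-category convention (derivatization-only peptides are
    unmodified)."""
    if histone_accessions is None:
        is_hist = lambda acc: True  # noqa: E731
    elif callable(histone_accessions):
        is_hist = histone_accessions
    else:
        accs = set(histone_accessions)
        is_hist = lambda acc: acc in accs  # noqa: E731

    total_mod = 0
    entrap_mod = 0
    breakdown: dict[str, dict[str, int]] = {}
    for p in psms:
        if p.is_decoy:
            continue
        origin = "entrapment" if p.spectrum_species == "entrapment" else "target"
        modified = assign_group(p, convention="folded2") == GROUP_BIOLOGICAL
        d = breakdown.setdefault(origin, {"modified": 0, "unmodified": 0})
        d["modified" if modified else "unmodified"] += 1
        histone_hit = (not p.is_entrapment) and any(
            is_hist(acc) for acc, _, _ in p.form.proteins
        )
        if modified and histone_hit:
            total_mod += 1
            if origin == "entrapment":
                entrap_mod += 1
    return EntrapmentReport(total_mod, entrap_mod, breakdown)
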