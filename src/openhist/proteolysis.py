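"""FASTA handling, in-silico digestion, derivatization chemistry and
peptidoform enumeration.

Histone bottom-up workflows block lysines chemically (propionylation or d3
acetylation) before trypsin digestion, so that the protease cleaves only
after arginine ("ArgC-like" pattern).  Where derivatization is incomplete,
genuinely tryptic peptides appear.  This module digests protein sequences
under those rules, applies the derivatization chemistry to each peptide
(a lysine is derivatized only when its epsilon-amine is free: acylations
and glycation adducts block it, mono-methylation does not), and enumerates
the combinatorial space of variably modified peptidoforms that the search
engine will consider.

Sites are numbered on the mature protein: the initiator methionine is
removed on loading by default so positions agree with histone nomenclature
(H3K9, H4K77, ...).
"""

from __future__ import annotations

import itertools
import logging
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from pyteomics import fasta as _pfasta
from pyteomics import mass as _pmass

from openhist.chemistry import (
    C_TERM,
    DERIVATIZATION,
    N_TERM,
    PROTEIN_N_TERM,
    Modification,
    Registry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinEntry",
    "DigestionRule",
    "Protocol",
    "PeptidoForm",
    "DigestedPeptide",
    "ARGC",
    "TRYPSIN",
    "read_fasta",
    "write_fasta",
    "add_decoys",
    "make_decoy",
    "is_histone",
    "bundled_histones",
    "digest",
    "apply_protocol",
    "enumerate_forms",
    "write_predigested_fasta",
    "read_predigested_fasta",
]

WATER = _pmass.calculate_mass(formula="H2O")
RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

DECOY_PREFIX = "rev_"
ENTRAPMENT_PREFIX = "entrap_"

#: description/accession patterns used to classify database entries as
#: histones (the spec of "histone sequences" is pattern-based, not a fixed
#: accession list; extend as needed)
HISTONE_PATTERNS = (
    r"\bhistone\b",
    r"\bH1\.\d",
    r"^H1[-_.]",
    r"^H2A",
    r"^H2B",
    r"^H3[._-]?",
    r"^H4[._-]?",
)
_HISTONE_RE = [re.compile(p, re.IGNORECASE) for p in HISTONE_PATTERNS]


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    description: str
    sequence: str
    is_decoy: bool = False
    is_entrapment: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def is_histone(entry: ProteinEntry) -> bool:
    if entry.is_decoy or entry.is_entrapment:
        return False
    text = f"{entry.accession} {entry.description}"
    return any(rx.search(text) for rx in _HISTONE_RE)


def _parse_header(header: str) -> tuple[str, str]:
    header = header.strip()
    first = header.split(None, 1)
    word = first[0]
    desc = first[1] if len(first) > 1 else ""
    if "|" in word:  # UniProt-style sp|P68431|H31_HUMAN
        parts = word.split("|")
        acc = parts[1] if len(parts) > 1 and parts[1] else parts[0]
    else:
        acc = word
    return acc, desc


def read_fasta(path: str | Path, strip_initiator_met: bool = True) -> list[ProteinEntry]:
    """Read a protein FASTA.  ``strip_initiator_met`` removes a leading M
    so that residue numbering matches the mature protein (histone
    convention); pass ``False`` to keep sequences verbatim."""
    entries = []
    with _pfasta.read(str(path)) as reader:
        for header, seq in reader:
            acc, desc = _parse_header(header)
            seq = seq.strip().upper()
            is_decoy = acc.startswith(DECOY_PREFIX)
            is_entrap = acc.startswith(ENTRAPMENT_PREFIX)
            if strip_initiator_met and seq.startswith("M") and not is_decoy:
                seq = seq[1:]
            entries.append(
                ProteinEntry(acc, desc, seq, is_decoy=is_decoy, is_entrapment=is_entrap)
            )
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            desc = f" {e.description}" if e.description else ""
            fh.write(f">{e.accession}{desc}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


_DATA_DIR = Path(__file__).parent / "data"


def bundled_histones(strip_initiator_met: bool = True) -> list[ProteinEntry]:
    """The compact bundled human core-histone panel (H3.1, H3.2, H3.3, H4)
    used by the synthetic-data generator and the worked examples."""
    return read_fasta(_DATA_DIR / "histones.fasta", strip_initiator_met)


def make_decoy(entry: ProteinEntry) -> ProteinEntry:
    """Decoy by sequence reversal with the C-terminal residue held in
    place, which preserves the C-side cleavage pattern."""
    seq = entry.sequence
    decoy_seq = seq[:-1][::-1] + seq[-1] if len(seq) > 1 else seq
    return ProteinEntry(
        DECOY_PREFIX + entry.accession,
        entry.description,
        decoy_seq,
        is_decoy=True,
        is_entrapment=entry.is_entrapment,
    )


def add_decoys(entries: Sequence[ProteinEntry]) -> list[ProteinEntry]:
    out = list(entries)
    out.extend(make_decoy(e) for e in entries if not e.is_decoy)
    return out


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigestionRule:
    """C-side proteolytic cleavage rule."""

    cleave_after: frozenset[str]
    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 35

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")


ARGC = DigestionRule(frozenset("R"))
TRYPSIN = DigestionRule(frozenset("KR"))


@dataclass(frozen=True)
class DigestedPeptide:
    sequence: str
    accession: str
    start: int  # 1-based inclusive on the mature protein
    end: int
    missed_cleavages: int = 0
    is_decoy: bool = False
    is_entrapment: bool = False


def digest(protein: ProteinEntry, rule: DigestionRule) -> list[DigestedPeptide]:
    """All peptides of ``protein`` under ``rule`` with at most
    ``max_missed_cleavages`` internal cleavage sites and length within
    bounds.  Coordinates are 1-based inclusive."""
    seq = protein.sequence
    if not seq:
        return []
    # segment boundaries: indices after which cleavage occurs
    cut_points = [0]
    for i, aa in enumerate(seq):
        if aa in rule.cleave_after and i + 1 < len(seq):
            cut_points.append(i + 1)
    cut_points.append(len(seq))
    segments = [
        (cut_points[i], cut_points[i + 1]) for i in range(len(cut_points) - 1)
    ]
    out = []
    for i in range(len(segments)):
        for j in range(i, min(i + rule.max_missed_cleavages + 1, len(segments))):
            start, end = segments[i][0], segments[j][1]
            pep = seq[start:end]
            if rule.min_length <= len(pep) <= rule.max_length:
                out.append(
                    DigestedPeptide(
                        pep,
                        protein.accession,
                        start + 1,
                        end,
                        missed_cleavages=j - i,
                        is_decoy=protein.is_decoy,
                        is_entrapment=protein.is_entrapment,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# derivatization protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """Derivatization chemistry applied during sample preparation.

    PRO-PIC: lysines propionylated, peptide N-termini capped with phenyl
    isocyanate.  PRO2: propionyl on both.  D3: d3-acetyl on both.
    ``none``: no fixed chemistry (the linker-histone H1 workflow).
    """

    name: str
    k_mod: Modification | None
    nterm_mod: Modification | None
    under_derivatization_allowed: bool = True

    @classmethod
    def preset(cls, name: str, registry: Registry) -> "Protocol":
        name_u = name.upper().replace("_", "-")
        if name_u in ("NONE", ""):
            return cls("none", None, None)
        if name_u == "PRO-PIC":
            return cls("PRO-PIC", registry["propionyl"], registry["phenyl-isocyanate"])
        if name_u == "PRO2":
            return cls("PRO2", registry["propionyl"], registry["propionyl"])
        if name_u == "D3":
            return cls("D3", registry["d3-acetyl"], registry["d3-acetyl"])
        raise ValueError(f"unknown protocol {name!r}")


# ---------------------------------------------------------------------------
# peptidoforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptidoForm:
    """A peptide with a localized set of modifications.

    Positions are 1-based within the peptide; 0 is the peptide N-terminus
    and ``len+1`` the C-terminus.  A position slot holds an ordered tuple
    of modifications because derivatization can stack on top of a
    biological mark (mono-methylated lysines are still propionylated).
    At most one *variable* (searched) modification is placed per slot.
    """

    sequence: str
    mods: tuple[tuple[int, tuple[Modification, ...]], ...] = ()
    proteins: tuple[tuple[str, int, int], ...] = ()
    is_decoy: bool = False
    is_entrapment: bool = False

    @classmethod
    def build(
        cls,
        sequence: str,
        mods: Mapping[int, Sequence[Modification]] | None = None,
        proteins: Sequence[tuple[str, int, int]] = (),
        is_decoy: bool = False,
        is_entrapment: bool = False,
    ) -> "PeptidoForm":
        mods = mods or {}
        packed = tuple(
            (pos, tuple(ms))
            for pos, ms in sorted(mods.items())
            if ms
        )
        for pos, ms in packed:
            if not 0 <= pos <= len(sequence) + 1:
                raise ValueError(f"mod position {pos} outside peptide")
        return cls(sequence, packed, tuple(proteins), is_decoy, is_entrapment)

    @property
    def mod_map(self) -> dict[int, tuple[Modification, ...]]:
        return dict(self.mods)

    def mod_mass_at(self, pos: int) -> float:
        return sum(m.mass for m in self.mod_map.get(pos, ()))

    @property
    def total_mod_mass(self) -> float:
        return sum(m.mass for _, ms in self.mods for m in ms)

    @property
    def neutral_mass(self) -> float:
        """Uncharged monoisotopic mass: residues + water + modifications."""
        m = WATER + sum(RESIDUE_MASS[aa] for aa in self.sequence)
        return m + self.total_mod_mass

    def n_mods(self, category: str | None = None) -> int:
        return sum(
            1
            for _, ms in self.mods
            for m in ms
            if category is None or m.category == category
        )

    def categories(self) -> set[str]:
        return {m.category for _, ms in self.mods for m in ms}

    def mod_names(self) -> list[tuple[int, str]]:
        return [(pos, m.name) for pos, ms in self.mods for m in ms]

    def with_added_mod(self, pos: int, mod: Modification) -> "PeptidoForm":
        mm = {p: list(ms) for p, ms in self.mods}
        mm.setdefault(pos, []).append(mod)
        return PeptidoForm.build(
            self.sequence, mm, self.proteins, self.is_decoy, self.is_entrapment
        )

    def assigned_mods_str(self) -> str:
        """psm.tsv-style assigned-modifications string ``pos(residue)mass``;
        N-term rendered as ``N-term``, C-term as ``C-term``."""
        parts = []
        for pos, ms in self.mods:
            for m in ms:
                if pos == 0:
                    where = "N-term"
                elif pos == len(self.sequence) + 1:
                    where = "C-term"
                else:
                    where = f"{pos}({self.sequence[pos - 1]})"
                parts.append(f"{where}{m.mass:+.4f}")
        return ", ".join(parts)

    def __str__(self) -> str:
        mm = self.mod_map
        out = []
        if 0 in mm:
            out.append("[" + "+".join(m.name for m in mm[0]) + "]-")
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if i in mm:
                out.append("(" + "+".join(m.name for m in mm[i]) + ")")
        return "".join(out)


def apply_protocol(
    peptide: DigestedPeptide | str,
    protocol: Protocol,
    biological_mods: Mapping[int, Modification] | None = None,
    derivatized: bool = True,
) -> PeptidoForm:
    """Combine a peptide with its biological modifications and the
    protocol's fixed chemistry.

    Every lysine whose epsilon-amine is free receives the protocol K
    modification; a lysine occupied by a blocking biological modification
    (acylations, glycation adducts, me2/me3) does not; mono-methylated
    lysines are still derivatized.  The peptide N-terminus receives the
    protocol N-terminal cap.  ``derivatized=False`` models an
    under-derivatized (tryptic) peptide: no fixed chemistry at all.
    """
    if isinstance(peptide, DigestedPeptide):
        seq = peptide.sequence
        proteins = ((peptide.accession, peptide.start, peptide.end),)
        is_decoy, is_entrap = peptide.is_decoy, peptide.is_entrapment
    else:
        seq = peptide
        proteins = ()
        is_decoy = is_entrap = False
    biological_mods = biological_mods or {}
    mods: dict[int, list[Modification]] = {
        pos: [m] for pos, m in biological_mods.items()
    }
    if derivatized and protocol.k_mod is not None:
        for i, aa in enumerate(seq, start=1):
            if aa != "K":
                continue
            occupant = biological_mods.get(i)
            if occupant is not None and occupant.blocks_lysine_derivatization:
                continue
            mods.setdefault(i, []).append(protocol.k_mod)
    if derivatized and protocol.nterm_mod is not None:
        mods.setdefault(0, []).append(protocol.nterm_mod)
    return PeptidoForm.build(seq, mods, proteins, is_decoy, is_entrap)


class CombinationCapExceeded(UserWarning):
    pass


def _variable_sites(
    seq: str,
    start: int,
    variable_mods: Iterable[Modification],
) -> list[tuple[int, Modification]]:
    """(position, modification) pairs at which each variable modification
    may be placed on the bare peptide."""
    pairs = []
    for mod in variable_mods:
        for i, aa in enumerate(seq, start=1):
            if mod.applies_to(aa):
                pairs.append((i, mod))
        if mod.applies_to(N_TERM):
            pairs.append((0, mod))
        if mod.applies_to(PROTEIN_N_TERM) and start == 1:
            pairs.append((0, mod))
        if mod.applies_to(C_TERM):
            pairs.append((len(seq) + 1, mod))
    return pairs


def enumerate_forms(
    peptide: DigestedPeptide | str,
    variable_mods: Iterable[Modification],
    max_var_mods: int = 5,
    protocol: Protocol | None = None,
    max_combinations: int = 99_000,
    derivatized: bool = True,
) -> list[PeptidoForm]:
    """All assignments of at most ``max_var_mods`` variable modifications
    (one per site) to the peptide, each combined with the protocol
    chemistry.  Enumeration is deterministic, fewest modifications first;
    if the combination cap is exceeded the list is truncated with a
    warning."""
    if max_var_mods < 0:
        raise ValueError("max_var_mods must be >= 0")
    if isinstance(peptide, DigestedPeptide):
        seq, start = peptide.sequence, peptide.start
    else:
        seq, start = peptide, 1
    protocol = protocol or Protocol("none", None, None)
    pairs = _variable_sites(seq, start, variable_mods)
    out: list[PeptidoForm] = []
    truncated = False
    for k in range(0, max_var_mods + 1):
        if truncated:
            break
        for combo in itertools.combinations(pairs, k):
            positions = [p for p, _ in combo]
            if len(set(positions)) != len(positions):
                continue  # one variable mod per site
            bio = {p: m for p, m in combo}
            out.append(
                apply_protocol(peptide, protocol, bio, derivatized=derivatized)
            )
            if len(out) >= max_combinations:
                warnings.warn(
                    f"combination cap {max_combinations} reached for "
                    f"peptide {seq}; enumeration truncated",
                    CombinationCapExceeded,
                )
                logger.warning(
                    "combination cap %d reached for %s", max_combinations, seq
                )
                truncated = True
                break
    return out


# ---------------------------------------------------------------------------
# sentinel-letter predigested FASTA (interoperability with engines that
# cannot place a mass offset on the N-terminus and the first residue
# simultaneously)
# ---------------------------------------------------------------------------

SENTINEL_LETTERS = ("B", "J")


def write_predigested_fasta(
    forms: Sequence[PeptidoForm],
    path: str | Path,
    sidecar_path: str | Path | None = None,
) -> dict[str, float]:
    """Emit each peptide as its own FASTA entry, prefixed with a sentinel
    letter (B or J) standing for its N-terminal fixed modification mass;
    a YAML sidecar maps sentinel letter to mass.  At most two distinct
    N-terminal masses can be encoded per file."""
    nterm_masses: list[float] = []
    assignments: list[tuple[PeptidoForm, float | None]] = []
    for f in forms:
        m = f.mod_mass_at(0)
        if m == 0.0:
            assignments.append((f, None))
            continue
        for known in nterm_masses:
            if abs(known - m) < 1e-9:
                m = known
                break
        else:
            nterm_masses.append(m)
        assignments.append((f, m))
    if len(nterm_masses) > len(SENTINEL_LETTERS):
        raise ValueError(
            f"{len(nterm_masses)} distinct N-terminal masses; at most "
            f"{len(SENTINEL_LETTERS)} per file — split the input"
        )
    letter_of = {m: SENTINEL_LETTERS[i] for i, m in enumerate(nterm_masses)}
    with open(path, "w") as fh:
        for idx, (f, m) in enumerate(assignments):
            prefix = letter_of[m] if m is not None else ""
            acc = f.proteins[0][0] if f.proteins else f"pep{idx}"
            fh.write(f">{acc}|pep{idx}\n{prefix}{f.sequence}\n")
    sidecar = {letter: m for m, letter in letter_of.items()}
    if sidecar_path is None:
        sidecar_path = str(path) + ".sentinels.yaml"
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump({"sentinel_masses": sidecar}, fh)
    return sidecar


def read_predigested_fasta(
    path: str | Path, sidecar_path: str | Path | None = None
) -> list[tuple[str, float]]:
    """Parse a sentinel-letter FASTA back into (peptide, N-term mass)
    pairs, stripping sentinel letters."""
    if sidecar_path is None:
        sidecar_path = str(path) + ".sentinels.yaml"
    with open(sidecar_path) as fh:
        sidecar = yaml.safe_load(fh)["sentinel_masses"] or {}
    out = []
    with _pfasta.read(str(path)) as reader:
        for _, seq in reader:
            seq = seq.strip().upper()
            if seq and seq[0] in sidecar:
                out.append((seq[1:], float(sidecar[seq[0]])))
            else:
                out.append((seq, 0.0))
    return out
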