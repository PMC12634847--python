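"""Theoretical fragment generation, MGF input/output, and the synthetic
spectrum generator.

The generator emulates data-dependent-acquisition HCD spectra of
derivatized histone peptides as acquired on an Orbitrap instrument:
ArgC-like peptides with propionylated lysines and phenyl-isocyanate-capped
N-termini, a configurable fraction of incomplete-derivatization tryptic
peptides, spiked biological modifications at planned protein sites,
chemical artifacts, uniform noise peaks, log-normal fragment intensities,
and an optional entrapment-species proteome with no histones.  Every
synthetic spectrum carries a truth record (the generating peptidoform and
its protein sites), which is what all end-to-end tests measure recovery
against.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pmgf

from openhist.chemistry import (
    BIOLOGICAL,
    CHEMICAL_ARTIFACT,
    Modification,
    Registry,
    default_registry,
)
from openhist.proteolysis import (
    ARGC,
    RESIDUE_MASS,
    TRYPSIN,
    WATER,
    DigestedPeptide,
    DigestionRule,
    PeptidoForm,
    Protocol,
    ProteinEntry,
    apply_protocol,
    bundled_histones,
    digest,
)

__all__ = [
    "PROTON",
    "FragmentIon",
    "FragmentSet",
    "Spectrum",
    "theoretical_fragments",
    "fragment_neutral_arrays",
    "SyntheticParams",
    "synthesize_spectrum",
    "read_mgf",
    "write_mgf",
    "write_truth",
    "read_truth",
    "SyntheticDataset",
    "generate_dataset",
    "random_proteome",
]

PROTON = 1.007276
ISOTOPE_SPACING = 1.00335  # Da, averagine C13-C12


@dataclass(frozen=True)
class FragmentIon:
    label: str  # e.g. "b3+" / "y5++" / "y5++ -CO2"
    series: str  # 'b' or 'y'
    index: int  # 1-based fragment number
    charge: int
    mz: float
    is_satellite: bool = False
    loss: str = ""


@dataclass(frozen=True)
class Spectrum:
    id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    provenance: dict | None = None  # truth record for synthetic data
    species: str | None = None

    def __post_init__(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity arrays differ in length")

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mz * self.precursor_charge - self.precursor_charge * PROTON

    def __len__(self) -> int:
        return len(self.mz)


def fragment_neutral_arrays(form: PeptidoForm) -> tuple[np.ndarray, np.ndarray]:
    """Neutral masses of the b1..b(L-1) and y1..y(L-1) fragments.

    The complementarity identity b_i + y_(L-i) = neutral peptide mass
    holds exactly by construction.
    """
    seq = form.sequence
    L = len(seq)
    site_mass = np.array(
        [RESIDUE_MASS[aa] + form.mod_mass_at(i) for i, aa in enumerate(seq, start=1)]
    )
    prefix = np.cumsum(site_mass)
    b = prefix[:-1] + form.mod_mass_at(0)
    # y_i for i = 1..L-1: suffix residues + water + C-terminal mod
    y = (prefix[-1] - prefix[:-1])[::-1] + WATER + form.mod_mass_at(L + 1)
    return b, y


def theoretical_fragments(
    form: PeptidoForm, charges: Sequence[int] = (1, 2)
) -> "FragmentSet":
    """All b/y ions of ``form`` at the requested fragment charges, plus
    neutral-loss satellite ions for every fragment containing a residue
    whose modification declares diagnostic neutral losses (CO2 for
    malonyl, phosphoric acid for phospho)."""
    b_neutral, y_neutral = fragment_neutral_arrays(form)
    L = len(form.sequence)
    ions: list[FragmentIon] = []
    # losses at residue positions: (position, loss formula, loss mass)
    losses = [
        (pos, nl.formula(), nl.mass())
        for pos, ms in form.mods
        if 1 <= pos <= L
        for m in ms
        for nl in m.diagnostic_neutral_losses
    ]
    for z in charges:
        zs = "+" * z
        for i in range(1, L):
            mz = (b_neutral[i - 1] + z * PROTON) / z
            ions.append(FragmentIon(f"b{i}{zs}", "b", i, z, mz))
            for pos, lname, lmass in losses:
                if pos <= i:
                    ions.append(
                        FragmentIon(
                            f"b{i}{zs} -{lname}", "b", i, z, mz - lmass / z,
                            is_satellite=True, loss=lname,
                        )
                    )
        for i in range(1, L):
            mz = (y_neutral[i - 1] + z * PROTON) / z
            ions.append(FragmentIon(f"y{i}{zs}", "y", i, z, mz))
            for pos, lname, lmass in losses:
                if pos > L - i:
                    ions.append(
                        FragmentIon(
                            f"y{i}{zs} -{lname}", "y", i, z, mz - lmass / z,
                            is_satellite=True, loss=lname,
                        )
                    )
    return FragmentSet(form=form, charges=tuple(charges), ions=tuple(ions))


@dataclass(frozen=True)
class FragmentSet:
    form: PeptidoForm
    charges: tuple[int, ...]
    ions: tuple[FragmentIon, ...]

    @property
    def primary(self) -> list[FragmentIon]:
        return [i for i in self.ions if not i.is_satellite]

    @property
    def satellites(self) -> list[FragmentIon]:
        return [i for i in self.ions if i.is_satellite]

    def n_theoretical(self, series: str) -> int:
        """Distinct primary fragment numbers per series (charge states of
        the same fragment count once)."""
        return len({i.index for i in self.ions if i.series == series and not i.is_satellite})


# ---------------------------------------------------------------------------
# synthetic spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticParams:
    """Noise model of the synthetic HCD spectra.

    ``detection_prob`` is the per-fragment detection probability;
    intensities of detected fragments are log-normal, noise peaks are
    uniform over ``noise_mz_range`` with low log-normal intensities;
    m/z jitter is Gaussian in ppm.  Precursors are generated calibrated
    (exact m/z), matching post-calibration instrument data.
    """

    detection_prob: float = 0.9
    n_noise_peaks: int = 20
    mz_jitter_ppm: float = 3.0
    noise_mz_range: tuple[float, float] = (100.0, 1500.0)
    signal_log_mean: float = np.log(1e5)
    signal_log_sigma: float = 0.7
    noise_log_mean: float = np.log(8e2)
    noise_log_sigma: float = 0.6
    fragment_charges: tuple[int, ...] = (1, 2)
    include_satellites: bool = True


def synthesize_spectrum(
    form: PeptidoForm,
    charge: int,
    params: SyntheticParams,
    rng: np.random.Generator,
    spectrum_id: str = "synthetic",
    species: str | None = None,
) -> Spectrum:
    """Deterministically (for a fixed generator state) synthesize one
    spectrum of ``form`` at the given precursor charge."""
    frags = theoretical_fragments(form, charges=params.fragment_charges)
    ions = list(frags.primary)
    if params.include_satellites:
        ions += frags.satellites
    mzs: list[float] = []
    intens: list[float] = []
    detected_labels: list[str] = []
    for ion in ions:
        if rng.random() < params.detection_prob:
            jitter = rng.normal(0.0, params.mz_jitter_ppm) * 1e-6 if params.mz_jitter_ppm else 0.0
            mzs.append(ion.mz * (1.0 + jitter))
            intens.append(float(rng.lognormal(params.signal_log_mean, params.signal_log_sigma)))
            detected_labels.append(ion.label)
    for _ in range(params.n_noise_peaks):
        mzs.append(float(rng.uniform(*params.noise_mz_range)))
        intens.append(float(rng.lognormal(params.noise_log_mean, params.noise_log_sigma)))
    mz_arr = np.array(mzs)
    int_arr = np.array(intens)
    order = np.argsort(mz_arr)
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    # merge coincident m/z to keep the peak list strictly sorted
    if len(mz_arr) > 1:
        keep = np.concatenate(([True], np.diff(mz_arr) > 0))
        if not keep.all():
            idx = np.cumsum(keep) - 1
            merged_int = np.zeros(keep.sum())
            np.add.at(merged_int, idx, int_arr)
            mz_arr, int_arr = mz_arr[keep], merged_int
    precursor_mz = (form.neutral_mass + charge * PROTON) / charge
    provenance = {
        "form": form,
        "peptide": form.sequence,
        "mods": form.assigned_mods_str(),
        "mod_names": form.mod_names(),
        "proteins": form.proteins,
        "charge": charge,
        "detected": detected_labels,
    }
    return Spectrum(
        id=spectrum_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        mz=mz_arr,
        intensity=int_arr,
        provenance=provenance,
        species=species,
    )


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------


def _validate_mgf_blocks(path: str | Path) -> None:
    depth = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if depth:
                    raise ValueError(f"{path}: nested BEGIN IONS at line {lineno}")
                depth = 1
            elif token == "END IONS":
                if not depth:
                    raise ValueError(f"{path}: END IONS without BEGIN at line {lineno}")
                depth = 0
    if depth:
        raise ValueError(f"{path}: unterminated BEGIN IONS block at end of file")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into Spectrum objects.  The TITLE field carries
    the spectrum id; a SPECIES field, if present, the species label."""
    _validate_mgf_blocks(path)
    out = []
    with _pmgf.read(str(path), use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 2
            pepmass = params.get("pepmass", (0.0,))[0]
            out.append(
                Spectrum(
                    id=str(params.get("title", f"scan{len(out)}")),
                    precursor_mz=float(pepmass),
                    precursor_charge=charge,
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                    species=params.get("species"),
                )
            )
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; m/z to 6 decimal places, intensity to 4
    significant digits, losslessly round-tripped by :func:`read_mgf`
    under that rounding."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            if s.species:
                fh.write(f"SPECIES={s.species}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.4g}\n")
            fh.write("END IONS\n")


def write_truth(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Tab-separated truth sidecar: spectrum_id, peptide, mod string,
    protein, charge, species."""
    rows = []
    for s in spectra:
        p = s.provenance or {}
        rows.append(
            {
                "spectrum_id": s.id,
                "peptide": p.get("peptide", ""),
                "modifications": p.get("mods", ""),
                "protein": ";".join(acc for acc, _, _ in p.get("proteins", ())),
                "charge": s.precursor_charge,
                "species": s.species or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# rough average amino-acid frequencies; enough R/K to digest
_AA_FREQ = np.array(
    [0.08, 0.02, 0.05, 0.06, 0.04, 0.07, 0.02, 0.06, 0.06, 0.09,
     0.02, 0.04, 0.05, 0.04, 0.06, 0.07, 0.06, 0.07, 0.01, 0.03]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def random_proteome(
    n_proteins: int,
    length: int,
    rng: np.random.Generator,
    prefix: str = "entrap_ECOLI",
    entrapment: bool = True,
) -> list[ProteinEntry]:
    """A synthetic stand-in proteome of random sequences (used for the
    entrapment species and for non-histone background proteins)."""
    out = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(list(_AA_ALPHABET), size=length, p=_AA_FREQ))
        out.append(
            ProteinEntry(
                f"{prefix}{i:03d}",
                "synthetic random-sequence protein",
                seq,
                is_entrapment=entrapment,
            )
        )
    return out


@dataclass
class SyntheticDataset:
    """A generated study: spectra with truth, the search database halves,
    and the site plan the generator spiked."""

    spectra: list[Spectrum]
    target_proteins: list[ProteinEntry]
    entrapment_proteins: list[ProteinEntry]  # entries present in the database
    site_plan: list[tuple[str, int, str]]  # (accession, mature position, mod name)
    registry: Registry
    protocol: Protocol

    @property
    def database(self) -> list[ProteinEntry]:
        return list(self.target_proteins) + list(self.entrapment_proteins)


def _position_in_protein(pep: DigestedPeptide, pos_in_pep: int) -> int:
    return pep.start + pos_in_pep - 1


def generate_dataset(
    n_spectra: int = 500,
    seed: int = 0,
    proteins: Sequence[ProteinEntry] | None = None,
    registry: Registry | None = None,
    protocol: str = "PRO-PIC",
    bio_mod_names: Sequence[str] = (
        "acetyl", "methyl", "dimethyl", "trimethyl", "formyl", "lactyl",
        "malonyl", "crotonyl", "butyryl", "glutaryl", "hydroxyisobutyryl",
        "phospho",
    ),
    n_sites: int = 15,
    modified_fraction: float = 0.6,
    artifact_rate: float = 0.10,
    artifact_names: Sequence[str] = ("propionyl-ST", "gel-artifact-13.98"),
    tryptic_fraction: float = 0.10,
    entrapment_fraction: float = 0.0,
    n_entrapment_proteins: int = 20,
    entrapment_protein_length: int = 250,
    entrapment_db_fraction: float = 1.0,
    params: SyntheticParams | None = None,
) -> SyntheticDataset:
    """Generate a seeded synthetic histone MS/MS study.

    A plan of ``n_sites`` (protein, position, modification) biological
    sites is drawn first; modified spectra are then sampled so that every
    planned site is supported by multiple spectra.  ``artifact_rate`` of
    spectra additionally carry a chemical artifact; ``tryptic_fraction``
    come from under-derivatized, fully tryptic peptides;
    ``entrapment_fraction`` come from a random-sequence entrapment
    proteome of which only ``entrapment_db_fraction`` of the proteins are
    present in the search database (emulating the incompleteness of any
    real database).
    """
    rng = np.random.default_rng(seed)
    registry = registry or default_registry()
    proteins = list(proteins) if proteins is not None else bundled_histones()
    proto = Protocol.preset(protocol, registry)
    params = params or SyntheticParams()
    bio_mods = [registry[n] for n in bio_mod_names]
    artifacts = [registry[n] for n in artifact_names]

    # --- digest targets under both rules -------------------------------
    argc_rule = DigestionRule(frozenset("R"), max_missed_cleavages=1,
                              min_length=6, max_length=30)
    tryp_rule = DigestionRule(frozenset("KR"), max_missed_cleavages=1,
                              min_length=6, max_length=30)
    argc_peps = [p for prot in proteins for p in digest(prot, argc_rule)]
    argc_seqs = {q.sequence for q in argc_peps}
    tryp_only = [
        p
        for prot in proteins
        for p in digest(prot, tryp_rule)
        if p.sequence not in argc_seqs
    ]
    if not argc_peps:
        raise ValueError("target proteins produced no ArgC peptides")

    # --- plan biological sites -----------------------------------------
    candidates: list[tuple[DigestedPeptide, int, Modification]] = []
    for pep in argc_peps:
        for i, aa in enumerate(pep.sequence, start=1):
            for mod in bio_mods:
                if mod.applies_to(aa):
                    candidates.append((pep, i, mod))
    order = rng.permutation(len(candidates))
    site_plan: list[tuple[str, int, str]] = []
    plan_entries: list[tuple[DigestedPeptide, int, Modification]] = []
    seen_sites: set[tuple[str, int]] = set()
    for idx in order:
        pep, pos, mod = candidates[idx]
        site = (pep.accession, _position_in_protein(pep, pos))
        if site in seen_sites:  # one modification per site keeps truth unambiguous
            continue
        seen_sites.add(site)
        site_plan.append((site[0], site[1], mod.name))
        plan_entries.append((pep, pos, mod))
        if len(site_plan) >= n_sites:
            break

    # --- entrapment proteome -------------------------------------------
    entrap_all = random_proteome(
        n_entrapment_proteins, entrapment_protein_length, rng
    ) if entrapment_fraction > 0 else []
    n_in_db = int(round(entrapment_db_fraction * len(entrap_all)))
    entrap_db = entrap_all[:n_in_db]
    entrap_peps = [p for prot in entrap_all for p in digest(prot, tryp_rule)]

    # --- sample spectra -------------------------------------------------
    spectra: list[Spectrum] = []
    n_entrap = int(round(entrapment_fraction * n_spectra))
    n_target = n_spectra - n_entrap
    n_tryptic = int(round(tryptic_fraction * n_target))
    for k in range(n_target):
        tryptic = k < n_tryptic and tryp_only
        if tryptic:
            pep = tryp_only[rng.integers(len(tryp_only))]
        else:
            pep = None
        bio: dict[int, Modification] = {}
        if rng.random() < modified_fraction and plan_entries:
            pidx = int(rng.integers(len(plan_entries)))
            planned_pep, pos, mod = plan_entries[pidx]
            if tryptic:
                # keep the tryptic peptide unmodified unless it covers a
                # planned site
                cover = [
                    (pp, pos2, m2)
                    for (pp, pos2, m2) in plan_entries
                    if pp.accession == pep.accession
                    and pep.start <= _position_in_protein(pp, pos2) <= pep.end
                    and m2.applies_to(pep.sequence[_position_in_protein(pp, pos2) - pep.start])
                ]
                if cover:
                    pp, pos2, m2 = cover[int(rng.integers(len(cover)))]
                    bio[_position_in_protein(pp, pos2) - pep.start + 1] = m2
            else:
                pep = planned_pep
                bio[pos] = mod
                # occasionally a second planned mark on the same peptide
                if rng.random() < 0.25:
                    others = [
                        (p2, m2)
                        for (pp, p2, m2) in plan_entries
                        if pp is planned_pep and p2 != pos
                    ]
                    if others:
                        p2, m2 = others[int(rng.integers(len(others)))]
                        bio[p2] = m2
        if pep is None:
            pep = argc_peps[int(rng.integers(len(argc_peps)))]
        form = apply_protocol(pep, proto, bio, derivatized=not tryptic)
        if rng.random() < artifact_rate:
            art = artifacts[int(rng.integers(len(artifacts)))]
            sites = [
                i
                for i, aa in enumerate(form.sequence, start=1)
                if art.applies_to(aa) and i not in bio
            ]
            if sites:
                form = form.with_added_mod(int(sites[int(rng.integers(len(sites)))]), art)
        charge = int(rng.choice([2, 3], p=[0.7, 0.3]))
        spectra.append(
            synthesize_spectrum(
                form, charge, params, rng,
                spectrum_id=f"target.{k:05d}", species="target",
            )
        )
    for k in range(n_entrap):
        if not entrap_peps:
            break
        pep = entrap_peps[int(rng.integers(len(entrap_peps)))]
        form = apply_protocol(pep, Protocol("none", None, None), {})
        charge = int(rng.choice([2, 3], p=[0.7, 0.3]))
        spectra.append(
            synthesize_spectrum(
                form, charge, params, rng,
                spectrum_id=f"entrap.{k:05d}", species="entrapment",
            )
        )
    perm = rng.permutation(len(spectra))
    spectra = [spectra[i] for i in perm]
    return SyntheticDataset(
        spectra=spectra,
        target_proteins=list(proteins),
        entrapment_proteins=entrap_db,
        site_plan=site_plan,
        registry=registry,
        protocol=proto,
    )
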