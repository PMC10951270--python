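"""Spectrum containers, peak-fragment matching, merging, consensus and I/O.

An :class:`AnnotatedSpectrum` holds intensities aligned to the theoretical
fragment index of its precursor (peptide part, glycan Y part, optional B
part); unmatched slots are zero.  Raw peak lists travel as :class:`Spectrum`
(read/written as MGF through pyteomics).  Datasets are stored as a directory
of TSV files plus a JSON manifest.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _pt_mgf

from .fragments import FragmentIndex, GlycopeptidePrecursor
from .glycans import parse_glycan_struct, serialize_canonical
from .peptides import Modification, PeptideSequence

__all__ = [
    "Spectrum",
    "AnnotatedSpectrum",
    "match_peaks",
    "merge_stepped_ce",
    "build_consensus",
    "passes_filters",
    "read_mgf",
    "write_mgf",
    "save_dataset",
    "load_dataset",
]


@dataclass
class Spectrum:
    """A raw peak list with precursor information."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class AnnotatedSpectrum:
    """Intensities aligned to the theoretical fragment index of a precursor."""

    index: FragmentIndex
    s_pep: np.ndarray
    s_y: np.ndarray
    s_b: np.ndarray
    ratio: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_pep = np.asarray(self.s_pep, dtype=float)
        self.s_y = np.asarray(self.s_y, dtype=float)
        self.s_b = np.asarray(self.s_b, dtype=float)
        if (
            self.s_pep.shape != (self.index.n_pep,)
            or self.s_y.shape != (self.index.n_y,)
            or self.s_b.shape != (self.index.n_b,)
        ):
            raise ValueError("intensity vectors do not match the fragment index")

    @property
    def precursor(self) -> GlycopeptidePrecursor:
        return self.index.precursor

    # matched-ion counts per class = occupied slots
    @property
    def matched_by(self) -> int:
        return int(np.count_nonzero(self.s_pep))

    @property
    def matched_Y(self) -> int:
        return int(np.count_nonzero(self.s_y))

    @property
    def matched_B(self) -> int:
        return int(np.count_nonzero(self.s_b))

    def glycan_vector(self) -> np.ndarray:
        return np.concatenate([self.s_y, self.s_b])

    def full_vector(self) -> np.ndarray:
        return np.concatenate([self.s_pep, self.s_y, self.s_b])

    def observed_ratio(self) -> float:
        """Peptide fraction of the total matched intensity."""
        pep = float(self.s_pep.sum())
        total = pep + float(self.s_y.sum()) + float(self.s_b.sum())
        return pep / total if total > 0 else 0.0

    def copy(self) -> "AnnotatedSpectrum":
        return AnnotatedSpectrum(
            self.index,
            self.s_pep.copy(),
            self.s_y.copy(),
            self.s_b.copy(),
            self.ratio,
            dict(self.metadata),
        )


def match_peaks(
    spec: Spectrum,
    precursor: GlycopeptidePrecursor,
    tol_ppm: float = 20.0,
    with_B: bool = False,
    index: FragmentIndex | None = None,
) -> AnnotatedSpectrum:
    """Assign peaks to theoretical fragments within a ppm tolerance.

    Each theoretical fragment receives the intensity of the closest matching
    peak; each peak is consumed by at most one fragment (smallest ppm error
    wins).  Glycan-bearing b/y variants accumulate into the slot of their
    naked channel.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if index is None:
        index = FragmentIndex(precursor, with_B=with_B)
    s_pep = np.zeros(index.n_pep)
    s_y = np.zeros(index.n_y)
    s_b = np.zeros(index.n_b)
    ions = index.theoretical_ions()
    pairs: list[tuple[float, int, int]] = []  # (|ppm|, ion_idx, peak_idx)
    mzs = spec.mz
    for k, (_part, _slot, ion) in enumerate(ions):
        if mzs.size == 0:
            break
        tol = ion.mz * tol_ppm * 1e-6
        lo = np.searchsorted(mzs, ion.mz - tol, side="left")
        hi = np.searchsorted(mzs, ion.mz + tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(mzs[j] - ion.mz) / ion.mz * 1e6, k, j))
    pairs.sort()
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    parts = {"pep": s_pep, "Y": s_y, "B": s_b}
    for _ppm, k, j in pairs:
        if k in used_ions or j in used_peaks:
            continue
        used_ions.add(k)
        used_peaks.add(j)
        part, slot, _ion = ions[k]
        parts[part][slot] += spec.intensity[j]
    out = AnnotatedSpectrum(index, s_pep, s_y, s_b, metadata=dict(spec.metadata))
    out.ratio = out.observed_ratio()
    return out


def _check_same_precursor(a: AnnotatedSpectrum, b: AnnotatedSpectrum) -> None:
    if a.precursor.key() != b.precursor.key():
        raise ValueError("annotated spectra have different precursors")


def merge_stepped_ce(
    low: AnnotatedSpectrum, high: AnnotatedSpectrum
) -> AnnotatedSpectrum:
    """Average two CE spectra into a pseudo stepped-CE spectrum."""
    _check_same_precursor(low, high)
    out = AnnotatedSpectrum(
        low.index,
        (low.s_pep + high.s_pep) / 2.0,
        (low.s_y + high.s_y) / 2.0,
        (low.s_b + high.s_b) / 2.0,
        metadata={**high.metadata, **low.metadata},
    )
    out.ratio = out.observed_ratio()
    return out


def _normalize_parts(spec: AnnotatedSpectrum) -> AnnotatedSpectrum:
    out = spec.copy()
    for v in (out.s_pep, out.s_y, out.s_b):
        t = v.sum()
        if t > 0:
            v /= t
    return out


def build_consensus(replicates: Sequence[AnnotatedSpectrum]) -> AnnotatedSpectrum:
    """Combine replicate spectra of one precursor into a consensus spectrum.

    Each replicate is normalized to unit total intensity per part and the
    normalized vectors are averaged; the peptide-fraction ratio is carried as
    the mean of the replicate ratios.  The result is invariant to replicate
    order and to per-replicate global intensity scaling.
    """
    if not replicates:
        raise ValueError("no replicates given")
    first = replicates[0]
    for r in replicates[1:]:
        _check_same_precursor(first, r)
    normed = [_normalize_parts(r) for r in replicates]
    out = AnnotatedSpectrum(
        first.index,
        np.mean([r.s_pep for r in normed], axis=0),
        np.mean([r.s_y for r in normed], axis=0),
        np.mean([r.s_b for r in normed], axis=0),
        metadata=dict(first.metadata),
    )
    out.ratio = float(np.mean([r.observed_ratio() for r in replicates]))
    return out


def passes_filters(
    spec: AnnotatedSpectrum,
    require_B: bool = False,
    min_by: int = 5,
    min_Y: int = 5,
    min_B: int = 2,
) -> bool:
    """Dataset quality filter: >=5 peptide b/y ions, >=5 Y ions, >=2 B ions."""
    if spec.matched_by < min_by or spec.matched_Y < min_Y:
        return False
    if require_B and spec.matched_B < min_B:
        return False
    return True


# ---------------------------------------------------------------------------
# MGF I/O


def read_mgf(path: str) -> list[Spectrum]:
    out = []
    with _pt_mgf.MGF(path) as reader:
        for entry in reader:
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (None,))
            charge = params.get("charge")
            out.append(
                Spectrum(
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    precursor_mz=pepmass[0] if pepmass else None,
                    precursor_charge=int(charge[0]) if charge else None,
                    metadata={"title": params.get("title", "")},
                )
            )
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str) -> None:
    entries = []
    for i, s in enumerate(spectra):
        params = {"title": s.metadata.get("title", f"spectrum_{i}")}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": params,
            }
        )
    with open(path, "w") as fh:
        _pt_mgf.write(entries, fh)


# ---------------------------------------------------------------------------
# Dataset container: directory of TSVs + JSON manifest


def _mods_to_str(mods: dict[int, Modification]) -> str:
    return ";".join(
        f"{pos}:{m.name}:{','.join(str(x) for x in m.elements)}"
        for pos, m in sorted(mods.items())
    )


def _mods_from_str(text: str) -> dict[int, Modification]:
    mods: dict[int, Modification] = {}
    if not text:
        return mods
    for item in text.split(";"):
        pos, name, elems = item.split(":")
        mods[int(pos)] = Modification(name, tuple(int(x) for x in elems.split(",")))
    return mods


def save_dataset(
    records: Sequence[AnnotatedSpectrum], path: str, manifest: dict | None = None
) -> None:
    """Write annotated spectra to ``path`` (created) as TSV + manifest JSON."""
    os.makedirs(path, exist_ok=True)
    with_B = any(r.index.with_B for r in records)
    with open(os.path.join(path, "precursors.tsv"), "w") as fh:
        fh.write(
            "id\tpeptide\tglycosite\tmodifications\tglycan_struct\tcharge\tratio\twith_B\n"
        )
        for i, r in enumerate(records):
            p = r.precursor
            fh.write(
                "\t".join(
                    [
                        str(i),
                        p.peptide.sequence,
                        str(p.peptide.glycosite),
                        _mods_to_str(p.peptide.modifications),
                        serialize_canonical(p.glycan),
                        str(p.charge),
                        "" if r.ratio is None else f"{r.ratio:.9g}",
                        str(int(r.index.with_B)),
                    ]
                )
                + "\n"
            )
    with open(os.path.join(path, "intensities.tsv"), "w") as fh:
        fh.write("id\tpart\tslot\tintensity\n")
        for i, r in enumerate(records):
            for part, vec in (("pep", r.s_pep), ("Y", r.s_y), ("B", r.s_b)):
                for slot in np.flatnonzero(vec):
                    fh.write(f"{i}\t{part}\t{slot}\t{vec[slot]:.9g}\n")
    meta = dict(manifest or {})
    meta.setdefault("n_records", len(records))
    meta.setdefault("with_B", bool(with_B))
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_dataset(path: str) -> tuple[list[AnnotatedSpectrum], dict]:
    """Read a dataset directory written by :func:`save_dataset`."""
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    records: list[AnnotatedSpectrum] = []
    order: list[str] = []
    by_id: dict[str, AnnotatedSpectrum] = {}
    with open(os.path.join(path, "precursors.tsv")) as fh:
        header = fh.readline()
        assert header.startswith("id\t")
        for line in fh:
            (rid, seq, site, mods, struct, charge, ratio, with_b) = line.rstrip(
                "\n"
            ).split("\t")
            pep = PeptideSequence(seq, int(site), _mods_from_str(mods))
            prec = GlycopeptidePrecursor(
                pep, parse_glycan_struct(struct), int(charge)
            )
            idx = FragmentIndex(prec, with_B=bool(int(with_b)))
            rec = AnnotatedSpectrum(
                idx,
                np.zeros(idx.n_pep),
                np.zeros(idx.n_y),
                np.zeros(idx.n_b),
                ratio=float(ratio) if ratio else None,
            )
            by_id[rid] = rec
            order.append(rid)
    with open(os.path.join(path, "intensities.tsv")) as fh:
        header = fh.readline()
        for line in fh:
            rid, part, slot, inten = line.rstrip("\n").split("\t")
            rec = by_id[rid]
            vec = {"pep": rec.s_pep, "Y": rec.s_y, "B": rec.s_b}[part]
            vec[int(slot)] = float(inten)
    records = [by_id[r] for r in order]
    return records, manifest
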