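"""Predicted spectral-library generation for DIA, with entrapment entries.

Libraries are flat transition-list TSVs, one fragment row per line, with
per-entry intensities normalized to max = 1.  Retention times are either
supplied externally (``PredMS2`` mode: predicted intensities, experimental
RT) or filled by a simple hydrophobicity-sum proxy (``PredLib`` mode; a
clearly tagged stand-in, not a trained RT model).  Entrapment entries —
glycopeptides known to be absent from the sample — are generated by swapping
library glycans for structures whose composition does not occur in the
library, in similar numbers to the library itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fragments import FragmentIndex, GlycopeptidePrecursor
from .glycans import GlycanTree, parse_glycan_struct, serialize_canonical
from .network import GlycoSpectrumNetwork
from .peptides import PeptideSequence

__all__ = [
    "LibraryEntry",
    "FragmentRow",
    "build_library",
    "generate_entrapment",
    "write_library",
    "read_library",
    "rt_proxy",
]

# Kyte-Doolittle hydropathy, used only by the RT proxy
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def rt_proxy(peptide: PeptideSequence) -> float:
    """Linear hydrophobicity-sum retention-time proxy (synthetic scale)."""
    return round(sum(_KD[a] for a in peptide.sequence) + 20.0, 4)


@dataclass(frozen=True)
class FragmentRow:
    series: str  # b, y, Y, B
    ordinal: int | None
    composition: str | None
    charge: int
    mz: float
    intensity: float


@dataclass
class LibraryEntry:
    precursor: GlycopeptidePrecursor
    precursor_mz: float
    rt: float
    fragments: list[FragmentRow] = field(default_factory=list)
    provenance: str = "predicted"

    @property
    def group_id(self) -> str:
        p = self.precursor
        return (
            f"{p.peptide.modified_string()}|{p.peptide.glycosite}|"
            f"{serialize_canonical(p.glycan)}|{p.charge}"
        )


def _entry_fragments(
    index: FragmentIndex, pred, top_n: int
) -> list[FragmentRow]:
    rows: list[tuple[float, FragmentRow]] = []
    seen = set()
    for part, slot, ion in index.theoretical_ions():
        if part == "pep" and ion.series not in ("b", "y"):
            continue
        if (part, slot) in seen:
            continue
        seen.add((part, slot))
        inten = {"pep": pred.full[: index.n_pep],
                 "Y": pred.full[index.n_pep : index.n_pep + index.n_y],
                 "B": pred.full[index.n_pep + index.n_y :]}[part][slot]
        if inten <= 0:
            continue
        rows.append(
            (
                inten,
                FragmentRow(
                    series=ion.series,
                    ordinal=ion.ordinal,
                    composition=str(ion.composition)
                    if ion.composition is not None
                    else None,
                    charge=ion.charge,
                    mz=ion.mz,
                    intensity=inten,
                ),
            )
        )
    rows.sort(key=lambda r: -r[0])
    rows = rows[:top_n]
    if not rows:
        return []
    peak = rows[0][0]
    return [
        FragmentRow(r.series, r.ordinal, r.composition, r.charge, r.mz,
                    r.intensity / peak)
        for _i, r in rows
    ]


def build_library(
    precursors: Sequence[GlycopeptidePrecursor],
    net: GlycoSpectrumNetwork,
    rt_source: Callable[[GlycopeptidePrecursor], float] | dict | None = None,
    mode: str = "PredMS2",
    top_n: int = 20,
) -> tuple[list[LibraryEntry], int]:
    """Predict a spectral library; returns (entries, n_skipped).

    ``PredMS2``: predicted intensities + supplied retention times
    (``rt_source`` required); ``PredLib``: predicted intensities + proxy RT.
    Precursors the model cannot handle (e.g. unsupported charge) are skipped.
    """
    if mode not in ("PredMS2", "PredLib"):
        raise ValueError(f"unknown library mode {mode!r}")
    if mode == "PredMS2" and rt_source is None:
        raise ValueError("PredMS2 mode requires an rt_source")
    entries: list[LibraryEntry] = []
    n_skipped = 0
    for prec in precursors:
        try:
            index = FragmentIndex(prec, with_B=net.config.with_B)
            pred = net.predict(index)
        except ValueError:
            n_skipped += 1
            continue
        if mode == "PredMS2":
            rt = (
                rt_source[prec.key()]
                if isinstance(rt_source, dict)
                else rt_source(prec)
            )
        else:
            rt = rt_proxy(prec.peptide)
        entries.append(
            LibraryEntry(
                precursor=prec,
                precursor_mz=prec.mz(),
                rt=float(rt),
                fragments=_entry_fragments(index, pred, top_n),
                provenance="predicted",
            )
        )
    return entries, n_skipped


def generate_entrapment(
    library: Sequence[LibraryEntry],
    glycan_space: Sequence[GlycanTree],
    net: GlycoSpectrumNetwork,
    seed: int,
    top_n: int = 20,
) -> list[LibraryEntry]:
    """Entrapment entries: library glycans swapped for foreign compositions.

    Foreign structures are those whose composition never occurs in the
    library, so every entrapment precursor is guaranteed absent; the count
    matches the library size (within 10%, else an error reports what was
    achievable).  Reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    lib_comps = {str(e.precursor.glycan.composition()) for e in library}
    foreign = [t for t in glycan_space if str(t.composition()) not in lib_comps]
    if not foreign:
        raise ValueError("no foreign-composition glycans available for entrapment")
    target = len(library)
    entries: list[LibraryEntry] = []
    seen = set()
    attempts = 0
    while len(entries) < target and attempts < 50 * target:
        attempts += 1
        base = library[int(rng.integers(len(library)))]
        tree = foreign[int(rng.integers(len(foreign)))]
        prec = GlycopeptidePrecursor(
            base.precursor.peptide, tree, base.precursor.charge
        )
        if prec.key() in seen:
            continue
        seen.add(prec.key())
        try:
            index = FragmentIndex(prec, with_B=net.config.with_B)
            pred = net.predict(index)
        except ValueError:
            continue
        entries.append(
            LibraryEntry(
                precursor=prec,
                precursor_mz=prec.mz(),
                rt=base.rt,
                fragments=_entry_fragments(index, pred, top_n),
                provenance="entrapment",
            )
        )
    if len(entries) < 0.9 * target:
        raise ValueError(
            f"could only generate {len(entries)} entrapment entries "
            f"for a library of {target}"
        )
    return entries


_HEADER = (
    "group_id\tpeptide\tmodified_sequence\tglycosite\tglycan_struct\t"
    "glycan_composition\tprecursor_charge\tprecursor_mz\trt\tprovenance\t"
    "fragment_series\tfragment_ordinal\tfragment_composition\t"
    "fragment_charge\tfragment_mz\trelative_intensity\n"
)


def write_library(entries: Sequence[LibraryEntry], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for e in entries:
            p = e.precursor
            prefix = "\t".join(
                [
                    e.group_id,
                    p.peptide.sequence,
                    p.peptide.modified_string(),
                    str(p.peptide.glycosite),
                    serialize_canonical(p.glycan),
                    str(p.glycan.composition()),
                    str(p.charge),
                    f"{e.precursor_mz:.6f}",
                    f"{e.rt:.4f}",
                    e.provenance,
                ]
            )
            for f in e.fragments:
                fh.write(
                    prefix
                    + "\t"
                    + "\t".join(
                        [
                            f.series,
                            "" if f.ordinal is None else str(f.ordinal),
                            f.composition or "",
                            str(f.charge),
                            f"{f.mz:.6f}",
                            f"{f.intensity:.6f}",
                        ]
                    )
                    + "\n"
                )


def read_library(path: str) -> list[LibraryEntry]:
    entries: dict[str, LibraryEntry] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_id\t"):
            raise ValueError("not a glycospec library TSV")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            (gid, seq, _mseq, site, struct, _comp, z, pmz, rt, prov,
             fs, fo, fc, fz, fmz, fi) = cols
            if gid not in entries:
                pep = PeptideSequence(seq, int(site))
                entries[gid] = LibraryEntry(
                    precursor=GlycopeptidePrecursor(
                        pep, parse_glycan_struct(struct), int(z)
                    ),
                    precursor_mz=float(pmz),
                    rt=float(rt),
                    provenance=prov,
                )
                order.append(gid)
            entries[gid].fragments.append(
                FragmentRow(
                    series=fs,
                    ordinal=int(fo) if fo else None,
                    composition=fc or None,
                    charge=int(fz),
                    mz=float(fmz),
                    intensity=float(fi),
                )
            )
    return [entries[g] for g in order]
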