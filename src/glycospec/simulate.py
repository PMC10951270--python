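"""Ground-truth glycopeptide spectrum simulator.

Provides a fully synthetic test bed in which the fragmentation rule is known
exactly: random tryptic-like glycopeptides with sequon-placed glycosites and
N-glycans grown on the canonical HexNAc2-Hex(1..3) core, and spectra whose Y
intensities follow a cleavage-propensity rule — each structure fragment gets
``exp(-sum of lambda over its boundary cleavages)`` with core cleavages less
likely than branch cleavages (lambda_core > lambda_branch), mirroring how
glycan cores survive low collision energies.  B-ion intensities decay with
fragment size with an oxonium boost for mono/disaccharides; peptide b/y ions
follow a smooth positional profile with residue-specific factors (enhanced
cleavage N-terminal to proline, suppressed C-terminal to it).  Parts are
mixed with a Beta-distributed peptide fraction, and the observed copy adds
multiplicative log-normal noise and random ion dropout.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .fragments import FragmentIndex, GlycopeptidePrecursor
from .glycans import GlycanTree, detect_core
from .peptides import PeptideSequence
from .spectra import AnnotatedSpectrum, Spectrum, passes_filters

__all__ = [
    "SimConfig",
    "simulate_precursors",
    "simulate_spectrum",
    "generate_dataset",
    "to_peak_list",
    "random_glycan",
    "glycan_space_for",
]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_precursors: int = 100
    peptide_length: tuple[int, int] = (7, 12)
    glycan_nodes: tuple[int, int] = (5, 9)
    class_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)  # HM, complex, hybrid
    p_core_fucose: float = 0.3
    p_bisecting: float = 0.2
    charges: tuple[int, int] = (2, 4)
    lambda_core: float = 1.2
    lambda_branch: float = 0.4
    ratio_mean: float = 0.25
    ratio_concentration: float = 10.0
    noise_cv: float = 0.10
    missing_rate: float = 0.05
    with_B: bool = False
    b_center: float = 0.35
    y_center: float = 0.55
    profile_width: float = 0.25

    def __post_init__(self) -> None:
        if self.lambda_core <= 0 or self.lambda_branch <= 0:
            raise ValueError("cleavage propensities must be positive")
        if self.noise_cv < 0 or not 0 <= self.missing_rate < 1:
            raise ValueError("invalid noise settings")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for k in ("peptide_length", "glycan_nodes", "class_mix", "charges"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# glycan generation


class _TreeBuilder:
    def __init__(self):
        self.codes: list[str] = []
        self.parent: list[int] = []

    def add(self, code: str, parent: int) -> int:
        self.codes.append(code)
        self.parent.append(parent)
        return len(self.codes) - 1

    def tree(self) -> GlycanTree:
        return GlycanTree(codes=list(self.codes), parent=list(self.parent))


def random_glycan(
    rng: np.random.Generator,
    glycan_class: str,
    n_nodes: int,
    core_fucose: bool,
    bisecting: bool,
) -> GlycanTree:
    """Grow a random N-glycan of the requested class on the canonical core."""
    b = _TreeBuilder()
    root = b.add("N", -1)
    n2 = b.add("N", root)
    bman = b.add("H", n2)
    arms = [b.add("H", bman), b.add("H", bman)]
    if core_fucose:
        b.add("F", root)
    if bisecting and glycan_class != "high_mannose":
        b.add("N", bman)
    budget = n_nodes - len(b.codes)

    def grow_hex_chain(arm: int, k: int) -> None:
        tips = [arm]
        for _ in range(k):
            tip = tips[int(rng.integers(len(tips)))]
            tips.append(b.add("H", tip))

    def grow_antenna(arm: int, k: int) -> int:
        """Attach a HexNAc-initiated antenna of up to k residues; returns used."""
        used = 0
        node = b.add("N", arm)
        antenna_n = node
        used += 1
        if used < k and rng.random() < 0.8:
            node = b.add("H", node)
            used += 1
            if used < k and rng.random() < 0.5:
                b.add("A" if rng.random() < 0.8 else "G", node)
                used += 1
        if used < k and rng.random() < 0.15:
            b.add("F", antenna_n)  # antennary (Lewis-type) fucosylation
            used += 1
        return used

    if glycan_class == "high_mannose":
        grow_hex_chain(arms[int(rng.integers(2))], max(budget, 0))
    elif glycan_class == "complex":
        budget = max(budget, 1)  # at least one antenna
        first = True
        while budget > 0:
            arm = arms[int(rng.integers(2))] if not first else arms[0]
            first = False
            budget -= grow_antenna(arm, budget)
    else:  # hybrid: one oligomannose arm, one antenna arm
        budget = max(budget, 2)
        n_hex = max(1, int(rng.integers(1, max(budget, 2))))
        n_hex = min(n_hex, budget - 1)
        grow_hex_chain(arms[0], n_hex)
        budget -= n_hex
        while budget > 0:
            budget -= grow_antenna(arms[1], budget)
    return b.tree()


def glycan_space_for(
    rng: np.random.Generator, n_structures: int = 200, config: SimConfig = SimConfig()
) -> list[GlycanTree]:
    """A synthetic glycan-structure database spanning the class mix."""
    classes = ("high_mannose", "complex", "hybrid")
    out: dict[str, GlycanTree] = {}
    lo, hi = config.glycan_nodes
    attempts = 0
    while len(out) < n_structures and attempts < 50 * n_structures:
        attempts += 1
        cls = classes[int(rng.choice(3, p=np.asarray(config.class_mix)))]
        t = random_glycan(
            rng,
            cls,
            int(rng.integers(lo, hi + 1)),
            rng.random() < config.p_core_fucose,
            rng.random() < config.p_bisecting,
        )
        out.setdefault(t.canonical(), t)
    return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# precursor generation

_AA_POOL = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptide(rng: np.random.Generator, length: int) -> PeptideSequence:
    seq = [_AA_POOL[int(rng.integers(20))] for _ in range(length)]
    seq[-1] = "K" if rng.random() < 0.5 else "R"
    site = int(rng.integers(0, length - 2))
    seq[site] = "N"
    seq[site + 2] = "S" if rng.random() < 0.5 else "T"
    return PeptideSequence("".join(seq), glycosite=site)


def simulate_precursors(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[GlycopeptidePrecursor]:
    """Random glycopeptide precursors with canonical-core glycans."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    classes = ("high_mannose", "complex", "hybrid")
    out = []
    lo_l, hi_l = config.peptide_length
    lo_g, hi_g = config.glycan_nodes
    lo_z, hi_z = config.charges
    for _ in range(config.n_precursors):
        pep = _random_peptide(rng, int(rng.integers(lo_l, hi_l + 1)))
        cls = classes[int(rng.choice(3, p=np.asarray(config.class_mix)))]
        tree = random_glycan(
            rng,
            cls,
            int(rng.integers(lo_g, hi_g + 1)),
            rng.random() < config.p_core_fucose,
            rng.random() < config.p_bisecting,
        )
        out.append(
            GlycopeptidePrecursor(pep, tree, int(rng.integers(lo_z, hi_z + 1)))
        )
    return out


# ---------------------------------------------------------------------------
# spectrum simulation


def _y_charge_weights(precursor_charge: int) -> np.ndarray:
    if precursor_charge <= 2:
        return np.array([0.75, 0.25, 0.0])
    if precursor_charge == 3:
        return np.array([0.5, 0.4, 0.1])
    return np.array([0.3, 0.45, 0.25])


_PEP_CHARGE_WEIGHTS = np.array([0.8, 0.2])


def _residue_factor(seq: str, cleavage: int) -> float:
    f = 1.0
    if seq[cleavage] == "P":  # cleavage N-terminal to proline: enhanced
        f *= 2.0
    if seq[cleavage - 1] == "P":  # C-terminal to proline: suppressed
        f *= 0.5
    if seq[cleavage - 1] == "G":
        f *= 0.8
    return f


def truth_structure_intensities(
    index: FragmentIndex, config: SimConfig
) -> tuple[dict[frozenset, float], dict[frozenset, float]]:
    """Noiseless per-structure-fragment intensities under the cleavage rule."""
    tree = index.precursor.glycan
    core = detect_core(tree)
    core_ids = core.core_node_ids

    def lam(site) -> float:
        if site.edge is None:
            return config.lambda_core
        _p, c = site.edge
        return config.lambda_core if c in core_ids else config.lambda_branch

    y_truth = {
        f.retained_ids: math.exp(-sum(lam(s) for s in f.cleavages))
        for f in index.y_structures
    }
    b_truth = {}
    for f in index.b_structures:
        size = len(f.retained_ids)
        inten = math.exp(-config.lambda_branch * (size - 1))
        if size <= 2:
            inten *= 4.0  # oxonium ions dominate
        b_truth[f.retained_ids] = inten
    return y_truth, b_truth


def simulate_spectrum(
    precursor: GlycopeptidePrecursor,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    index: FragmentIndex | None = None,
) -> tuple[AnnotatedSpectrum, AnnotatedSpectrum]:
    """Simulate one precursor; returns (observed, noiseless truth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if index is None:
        index = FragmentIndex(precursor, with_B=config.with_B)
    y_truth, b_truth = truth_structure_intensities(index, config)

    s_y = np.zeros(index.n_y)
    zw = _y_charge_weights(precursor.charge)
    for ci, (_comp, members) in enumerate(index.y_groups):
        total = sum(y_truth[m.retained_ids] for m in members)
        for z in (1, 2, 3):
            s_y[index.y_slot(ci, z)] = total * zw[z - 1]

    s_b = np.zeros(index.n_b)
    for ci, (_comp, members) in enumerate(index.b_groups):
        s_b[ci] = sum(b_truth[m.retained_ids] for m in members)

    pep = precursor.peptide
    L = len(pep)
    s_pep = np.zeros(index.n_pep)
    w = config.profile_width
    for i in range(1, L):
        pos = i / L
        f = _residue_factor(pep.sequence, i)
        base_b = math.exp(-((pos - config.b_center) ** 2) / (2 * w * w)) * f
        base_y = math.exp(-((pos - config.y_center) ** 2) / (2 * w * w)) * f
        for z in (1, 2):
            s_pep[index.pep_slot(i, "b", z)] = base_b * _PEP_CHARGE_WEIGHTS[z - 1]
            s_pep[index.pep_slot(i, "y", z)] = base_y * _PEP_CHARGE_WEIGHTS[z - 1]

    # mix parts with the peptide fraction
    a = config.ratio_mean * config.ratio_concentration
    bpar = (1.0 - config.ratio_mean) * config.ratio_concentration
    r = float(rng.beta(a, bpar))
    s_pep *= r / s_pep.sum()
    gly_total = s_y.sum() + s_b.sum()
    s_y *= (1.0 - r) / gly_total
    s_b *= (1.0 - r) / gly_total

    truth = AnnotatedSpectrum(
        index, s_pep.copy(), s_y.copy(), s_b.copy(), ratio=r
    )
    truth.metadata["y_structure_truth"] = y_truth
    truth.metadata["b_structure_truth"] = b_truth

    # observed copy: multiplicative log-normal noise + random ion dropout
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    obs_parts = []
    for vec in (s_pep, s_y, s_b):
        v = vec.copy()
        nz = np.flatnonzero(v)
        if sigma > 0 and nz.size:
            v[nz] *= rng.lognormal(-0.5 * sigma * sigma, sigma, size=nz.size)
        if config.missing_rate > 0 and nz.size:
            drop = nz[rng.random(nz.size) < config.missing_rate]
            v[drop] = 0.0
        obs_parts.append(v)
    observed = AnnotatedSpectrum(index, *obs_parts)
    observed.ratio = observed.observed_ratio()
    return observed, truth


def generate_dataset(
    config: SimConfig,
) -> tuple[list[AnnotatedSpectrum], list[AnnotatedSpectrum], dict]:
    """Simulate a filtered dataset: (observed, truths, manifest).

    One spectrum per unique precursor; spectra failing the matched-ion
    filters are discarded and regenerated.  The manifest round-trips the
    configuration exactly, so the dataset regenerates bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    observed: list[AnnotatedSpectrum] = []
    truths: list[AnnotatedSpectrum] = []
    seen: set = set()
    attempts = 0
    max_attempts = 50 * config.n_precursors
    while len(observed) < config.n_precursors and attempts < max_attempts:
        attempts += 1
        prec = simulate_precursors(
            SimConfig(**{**config.to_dict(), "n_precursors": 1}), rng
        )[0]
        if prec.key() in seen:
            continue
        obs, truth = simulate_spectrum(prec, config, rng)
        if not passes_filters(obs, require_B=config.with_B):
            continue
        seen.add(prec.key())
        observed.append(obs)
        truths.append(truth)
    manifest = {"sim_config": config.to_dict(), "n_records": len(observed)}
    return observed, truths, manifest


def to_peak_list(rec: AnnotatedSpectrum, rng=None) -> Spectrum:
    """Render an annotated spectrum as a raw peak list at theoretical m/z.

    Peptide-slot intensity is placed at the naked b/y ion m/z.
    """
    mz = []
    inten = []
    seen_slots = set()
    for part, slot, ion in rec.index.theoretical_ions():
        if part == "pep" and ion.series not in ("b", "y"):
            continue
        if (part, slot) in seen_slots:
            continue
        seen_slots.add((part, slot))
        vec = {"pep": rec.s_pep, "Y": rec.s_y, "B": rec.s_b}[part]
        if vec[slot] > 0:
            mz.append(ion.mz)
            inten.append(vec[slot])
    prec = rec.precursor
    return Spectrum(
        np.array(mz),
        np.array(inten),
        precursor_mz=prec.mz(),
        precursor_charge=prec.charge,
        metadata={"title": "|".join(str(x) for x in prec.key())},
    )
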