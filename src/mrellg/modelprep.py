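"""Predicted-model preparation for molecular replacement.

Structure-prediction pipelines report a per-residue estimate of coordinate
error, either directly as Delta in angstroms (CASP convention, stored in
the B-factor column) or as pLDDT (AlphaFold depositions).  Before a model
is used for phasing it is (a) trimmed: residues whose predicted error
exceeds a threshold are removed, and (b) weighted: the error is converted
to an isotropic B factor through B = 8 pi^2 Delta^2 / 3 so that poorly
predicted atoms contribute less at high resolution.

PDB is the required dialect (gemmi handles parsing); mmCIF files that
gemmi recognises are accepted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import gemmi
import numpy as np

from .crystal import UnitCell
from .diffraction import AtomicModel, scattering_factor
from .scoring import superpose

__all__ = [
    "PredictedModel",
    "Ensemble",
    "read_model",
    "write_model",
    "error_to_bfactor",
    "plddt_to_delta",
    "trim_by_error",
    "ensemble_divergence_trim",
    "estimate_fm",
    "asu_scattering_from_sequence",
    "read_fasta_sequence",
]

_MODES = ("delta-angstrom", "plddt", "plain-b")


class EmptyModelError(ValueError):
    pass


@dataclass
class PredictedModel:
    """An atomic model plus per-residue predicted error.

    mode 'delta-angstrom': the B column held Delta (A) directly.
    mode 'plddt':          the B column held pLDDT; converted to Delta.
    mode 'plain-b':        ordinary B factors, no error estimate.
    ``delta`` maps (chain_id, res_seq) -> Delta; None in plain-b mode.
    """

    atoms: AtomicModel
    mode: str
    delta: dict[tuple[str, int], float] | None = None
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.mode != "plain-b":
            if self.delta is None:
                raise ValueError("error estimates required outside plain-b mode")
            if any(d < 0 for d in self.delta.values()):
                raise ValueError("predicted errors must be non-negative")
            missing = set(self.residue_ids()) - set(self.delta)
            if missing:
                raise ValueError(f"residues without an error estimate: {sorted(missing)[:5]}")

    def residue_ids(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.atoms.chain_ids, self.atoms.res_seq):
            seen.setdefault((c, int(r)), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids())

    @property
    def delta_per_atom(self) -> np.ndarray | None:
        if self.delta is None:
            return None
        return np.array([self.delta[(c, int(r))]
                         for c, r in zip(self.atoms.chain_ids, self.atoms.res_seq)])

    def ca_coords(self) -> np.ndarray:
        """Orthogonal coordinates of one representative atom per residue (CA
        when present, else the residue's first atom)."""
        orth = self.atoms.cell.orthogonalize(self.atoms.frac)
        best: dict[tuple[str, int], int] = {}
        for i, (c, r, name) in enumerate(zip(self.atoms.chain_ids, self.atoms.res_seq,
                                             self.atoms.atom_names)):
            key = (c, int(r))
            if key not in best or name.strip().upper() == "CA":
                best[key] = i
        return orth[[best[k] for k in self.residue_ids()]]


@dataclass
class Ensemble:
    """Predicted models sharing a residue numbering (e.g. the five
    submissions for one target)."""

    members: list[PredictedModel]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")

    def __len__(self) -> int:
        return len(self.members)

    def common_residues(self) -> list[tuple[str, int]]:
        common = set(self.members[0].residue_ids())
        for m in self.members[1:]:
            common &= set(m.residue_ids())
        return [rid for rid in self.members[0].residue_ids() if rid in common]


# -- I/O --------------------------------------------------------------------

_DEFAULT_CELL = UnitCell(1.0, 1.0, 1.0)  # placeholder when CRYST1 is absent


def read_model(path, mode: str = "delta-angstrom") -> PredictedModel:
    """Read a PDB (or mmCIF) file into a PredictedModel.

    The per-residue error estimate is the B value of the residue's CA atom
    (first atom as fallback), matching the per-residue convention of
    predicted-error records.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path} contains no model")
    c = st.cell
    cell = (UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
            if c.is_crystal() else _DEFAULT_CELL)
    frac, elements, occ, b = [], [], [], []
    chain_ids, res_seq, atom_names = [], [], []
    delta: dict[tuple[str, int], float] = {}
    for chain in st[0]:
        for res in chain:
            rep_b = None
            for atom in res:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                frac.append(pos)
                elements.append(atom.element.name)
                occ.append(atom.occ)
                b.append(max(atom.b_iso, 0.0))
                chain_ids.append(chain.name)
                res_seq.append(res.seqid.num)
                atom_names.append(atom.name)
                if rep_b is None or atom.name.strip().upper() == "CA":
                    rep_b = atom.b_iso
            if rep_b is not None:
                delta[(chain.name, res.seqid.num)] = rep_b
    if not frac:
        raise EmptyModelError(f"{path} contains no atoms")
    model = AtomicModel(cell, cell.fractionalize(np.array(frac)), elements,
                        np.clip(np.array(occ), 0.0, 1.0), np.array(b),
                        chain_ids, np.array(res_seq), atom_names)
    if mode == "plain-b":
        return PredictedModel(model, mode, None)
    if mode == "plddt":
        delta = {k: plddt_to_delta(v) for k, v in delta.items()}
    bad = {k: v for k, v in delta.items() if v < 0}
    if bad:
        raise ValueError(f"negative error estimates for residues {sorted(bad)[:5]}")
    return PredictedModel(model, mode, delta)


def write_model(model: PredictedModel, path, b_policy: str = "original") -> None:
    """Write standard PDB ATOM records (orthogonal A, CRYST1 from the cell).

    b_policy 'delta-converted' writes B = 8 pi^2 Delta^2 / 3 per atom;
    'original' writes the stored B values.
    """
    if b_policy not in ("original", "delta-converted"):
        raise ValueError("b_policy must be 'original' or 'delta-converted'")
    atoms = model.atoms
    if len(atoms) == 0:
        raise EmptyModelError("refusing to write an empty model")
    if b_policy == "delta-converted":
        if model.delta is None:
            raise ValueError("delta-converted policy needs error estimates")
        b_out = error_to_bfactor(model.delta_per_atom)
    else:
        b_out = atoms.b
    st = gemmi.Structure()
    st.cell = atoms.cell.to_gemmi()
    st.spacegroup_hm = "P 1"
    gm = gemmi.Model("1")
    orth = atoms.cell.orthogonalize(atoms.frac)
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(len(atoms)):
        cid = atoms.chain_ids[i]
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        chain = chain_map[cid]
        seq = int(atoms.res_seq[i])
        if len(chain) == 0 or chain[-1].seqid.num != seq:
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(seq, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = atoms.atom_names[i]
        atom.element = gemmi.Element(atoms.elements[i])
        atom.pos = gemmi.Position(*orth[i])
        atom.occ = float(atoms.occ[i])
        atom.b_iso = float(b_out[i])
        chain[-1].add_atom(atom)
    for chain in chain_map.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# -- error handling and trimming --------------------------------------------


def error_to_bfactor(delta):
    """B = 8 pi^2 Delta^2 / 3 (A^2); Delta in angstroms."""
    delta_arr = np.asarray(delta, dtype=float)
    if np.any(delta_arr < 0):
        raise ValueError("predicted error must be non-negative")
    b = 8.0 * math.pi**2 * delta_arr**2 / 3.0
    return float(b) if np.isscalar(delta) or delta_arr.ndim == 0 else b


def plddt_to_delta(plddt: float) -> float:
    """Monotone pLDDT (0-100) -> approximate coordinate error (A).

    Delta = 1.5 * exp(4 * (0.7 - plddt/100)), the empirical mapping used when
    processing predicted models for phasing.  An approximation: pLDDT is a
    local superposition score, not a direct distance error.
    """
    if not 0.0 <= plddt <= 100.0:
        raise ValueError("pLDDT must lie in [0, 100]")
    return 1.5 * math.exp(4.0 * (0.7 - plddt / 100.0))


def trim_by_error(model: PredictedModel, threshold: float) -> PredictedModel:
    """Remove every residue whose predicted error exceeds the threshold.

    Atom order is otherwise preserved; the returned model records the
    retained-residue fraction.  Raises EmptyModelError when nothing is left.
    """
    if model.mode != "delta-angstrom":
        raise ValueError("trimming requires delta-angstrom error estimates")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    assert model.delta is not None
    keep_res = {rid for rid, d in model.delta.items() if d <= threshold}
    if not keep_res:
        raise EmptyModelError("error threshold removes every residue")
    mask = np.array([(c, int(r)) in keep_res
                     for c, r in zip(model.atoms.chain_ids, model.atoms.res_seq)])
    retained = len(keep_res) / model.n_residues
    return PredictedModel(model.atoms.subset(mask), model.mode,
                          {k: v for k, v in model.delta.items() if k in keep_res},
                          retained_fraction=retained)


def ensemble_divergence_trim(ensemble: Ensemble, divergence_threshold: float) -> Ensemble:
    """Trim residues where ensemble members disagree.

    All members are superposed onto the first (least squares over the common
    core of CA atoms); a residue is removed from every member when its
    maximum pairwise CA divergence exceeds the threshold.
    """
    if len(ensemble) < 2:
        raise ValueError("divergence trimming needs at least two members")
    if divergence_threshold <= 0:
        raise ValueError("divergence threshold must be positive")
    common = ensemble.common_residues()
    if len(common) < 3:
        raise ValueError("fewer than three residues in the ensemble common core")
    coords = []
    for m in ensemble.members:
        idx = {rid: i for i, rid in enumerate(m.residue_ids())}
        coords.append(m.ca_coords()[[idx[rid] for rid in common]])
    ref = coords[0]

    def divergence(weights_idx) -> np.ndarray:
        aligned = [ref]
        for xyz in coords[1:]:
            sup = superpose(ref[weights_idx], xyz[weights_idx])
            aligned.append(xyz @ sup.rotation.T + sup.translation)
        arr = np.stack(aligned)                  # (m, n, 3)
        diff = arr[:, None] - arr[None, :]       # (m, m, n, 3)
        return np.max(np.linalg.norm(diff, axis=-1), axis=(0, 1))

    # two passes: a first global superposition, then a consensus refit on
    # the better-agreeing half so one displaced residue cannot smear small
    # divergences over the whole chain
    per_res = divergence(np.arange(len(common)))
    inliers = np.flatnonzero(per_res <= np.median(per_res))
    if len(inliers) >= 3:
        per_res = divergence(inliers)
    keep = {rid for rid, dv in zip(common, per_res) if dv <= divergence_threshold}
    if not keep:
        raise EmptyModelError("divergence threshold removes every residue")
    trimmed = []
    for m in ensemble.members:
        mask = np.array([(c, int(r)) in keep
                         for c, r in zip(m.atoms.chain_ids, m.atoms.res_seq)])
        delta = (None if m.delta is None
                 else {k: v for k, v in m.delta.items() if k in keep})
        trimmed.append(PredictedModel(m.atoms.subset(mask), m.mode, delta,
                                      retained_fraction=len(keep) / m.n_residues))
    return Ensemble(trimmed)


# -- scattering fraction ----------------------------------------------------


def estimate_fm(model: PredictedModel, asu_total_scattering: float) -> float:
    """Fraction of the asymmetric unit's total scattering in the model:
    sum over model atoms of (occ * f)^2 divided by the asu total."""
    if asu_total_scattering <= 0:
        raise ValueError("asu total scattering must be positive")
    fm = model.atoms.total_scattering / asu_total_scattering
    if fm > 1.0 + 1e-9:
        raise ValueError("model scattering exceeds the stated asu contents")
    return min(fm, 1.0)


#: Heavy-atom counts (C, N, O, S) per amino-acid residue, peptide-bonded
#: (one water removed relative to the free amino acid).
_RESIDUE_ATOMS = {
    "A": {"C": 3, "N": 1, "O": 1}, "R": {"C": 6, "N": 4, "O": 1},
    "N": {"C": 4, "N": 2, "O": 2}, "D": {"C": 4, "N": 1, "O": 3},
    "C": {"C": 3, "N": 1, "O": 1, "S": 1}, "Q": {"C": 5, "N": 2, "O": 2},
    "E": {"C": 5, "N": 1, "O": 3}, "G": {"C": 2, "N": 1, "O": 1},
    "H": {"C": 6, "N": 3, "O": 1}, "I": {"C": 6, "N": 1, "O": 1},
    "L": {"C": 6, "N": 1, "O": 1}, "K": {"C": 6, "N": 2, "O": 1},
    "M": {"C": 5, "N": 1, "O": 1, "S": 1}, "F": {"C": 9, "N": 1, "O": 1},
    "P": {"C": 5, "N": 1, "O": 1}, "S": {"C": 3, "N": 1, "O": 2},
    "T": {"C": 4, "N": 1, "O": 2}, "W": {"C": 11, "N": 2, "O": 1},
    "Y": {"C": 9, "N": 1, "O": 2}, "V": {"C": 5, "N": 1, "O": 1},
}


def asu_scattering_from_sequence(sequence: str, n_copies: int = 1) -> float:
    """Total scattering (sum f^2 over heavy atoms) of n_copies of a protein
    sequence, using point-atom factors.  Unknown letters raise."""
    if n_copies < 1:
        raise ValueError("need at least one copy")
    total = 0.0
    for aa in sequence.strip().upper():
        if aa in ("*", "-", " "):
            continue
        try:
            comp = _RESIDUE_ATOMS[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r}") from None
        total += sum(n * scattering_factor(el) ** 2 for el, n in comp.items())
    return total * n_copies


def read_fasta_sequence(path) -> str:
    """First sequence of a FASTA file."""
    seq: list[str] = []
    with open(path) as fh:
        started = False
        for line in fh:
            if line.startswith(">"):
                if started:
                    break
                started = True
                continue
            seq.append(line.strip())
    if not seq:
        raise ValueError(f"no sequence found in {path}")
    return "".join(seq)
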