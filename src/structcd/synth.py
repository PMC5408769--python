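"""Synthetic fixture generation: structures with known architecture and
spectra following a known structure->spectrum law.

Structures are built from ideal backbone internal coordinates (NeRF chain
construction) so that the hydrogen-bond based assigner recovers the intended
helix/strand labels; spectra mix three fixed Gaussian component curves
(helix-like, strand-like, other-like) weighted by the entry's secondary
structure fractions, optionally with Gaussian noise. The generator exists to
exercise the pipeline: backbone geometry targets assigner compatibility,
not stereochemical perfection, and the spectrum law is a fixture constant,
not a physical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .secstruct import assign_ss
from .spectra import Spectrum, WavelengthGrid, write_spectrum
from .structure import Chain, ProteinStructure, Residue

__all__ = ["SynthSpec", "SpectrumLaw", "make_helix", "make_sheet", "make_coil",
           "make_entry", "make_basis", "write_pdb", "build_backbone",
           "build_architecture", "fragments_to_structure", "default_mixes"]

# ideal backbone internal coordinates (lengths in A, angles in degrees)
_B_NCA, _B_CAC, _B_CN, _B_CO = 1.458, 1.525, 1.329, 1.231
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.8
_PHI_HELIX, _PSI_HELIX = -57.0, -47.0
_PHI_STRAND, _PSI_STRAND = -139.0, 135.0

# rigid transform relating adjacent antiparallel strands, calibrated once so
# that the Kabsch-Sander assigner sees the inter-strand hydrogen bonds. The
# propeller twist keeps strand-pair angles clear of the 30-degree histogram
# bin boundaries (an exactly antiparallel pair sits on the 180 boundary and
# its bin would flip on coordinate rounding); see docs/methods.md
_SHEET_TWIST_DEG = 6.0
_ANTI_OFFSET = np.array([3.5, 4.5, -0.25])
_PARA_OFFSET = np.array([0.0, 4.4, -2.0])


def _rot_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A-B-C with |CD|=bond, angle(BCD), torsion(ABCD)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Build backbone atoms (N, CA, C, O per residue) from (phi, psi) pairs.

    Omega is fixed at 180 degrees (trans peptide). The first residue's phi is
    unused; the last residue's psi orients only its carbonyl oxygen.
    """
    n_res = len(torsions)
    if n_res < 1:
        raise ValueError("need at least one residue")
    atoms: list[dict[str, np.ndarray]] = []
    # seed the first three atoms in a canonical pose
    n0 = np.zeros(3)
    ca0 = np.array([_B_NCA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A_NCAC)
    c0 = ca0 + _B_CAC * np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = atoms[-1]
        psi_prev = torsions[i - 1][1]
        n_i = _nerf(prev["N"], prev["CA"], prev["C"], _B_CN, _A_CACN, psi_prev)
        ca_i = _nerf(prev["CA"], prev["C"], n_i, _B_NCA, _A_CNCA, 180.0)
        phi_i = torsions[i][0]
        c_i = _nerf(prev["C"], n_i, ca_i, _B_CAC, _A_NCAC, phi_i)
        atoms.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(atoms):
        psi = torsions[i][1]
        res["O"] = _nerf(res["N"], res["CA"], res["C"], _B_CO, _A_CACO, psi + 180.0)
    return atoms


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _principal_axis(ca: np.ndarray) -> np.ndarray:
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    return d if np.dot(d, ca[-1] - ca[0]) > 0 else -d


def _transform(atoms: list[dict[str, np.ndarray]], rot: np.ndarray,
               shift: np.ndarray) -> list[dict[str, np.ndarray]]:
    return [{k: rot @ v + shift for k, v in res.items()} for res in atoms]


def _orient(atoms: list[dict[str, np.ndarray]], origin: np.ndarray,
            axis: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Rotate the fragment's CA principal axis onto ``axis``, centroid to origin."""
    ca = np.array([r["CA"] for r in atoms])
    rot = _rotation_between(_principal_axis(ca), np.asarray(axis, dtype=float))
    centroid = ca.mean(axis=0)
    return [{k: rot @ (v - centroid) + origin for k, v in res.items()}
            for res in atoms]


def make_helix(n_res: int, origin=(0.0, 0.0, 0.0),
               axis=(0.0, 0.0, 1.0)) -> list[dict[str, np.ndarray]]:
    """Ideal alpha-helix backbone fragment (phi=-57, psi=-47).

    Centroid sits at ``origin`` with the helix axis along ``axis`` (N to C).
    Returns per-residue atom dictionaries.
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    atoms = build_backbone([(_PHI_HELIX, _PSI_HELIX)] * n_res)
    return _orient(atoms, np.asarray(origin, dtype=float), np.asarray(axis, float))


def make_sheet(n_strands: int, n_res: int, spacing: float = 4.5,
               antiparallel: bool = True) -> list[list[dict[str, np.ndarray]]]:
    """Extended strands laid side by side with hydrogen-bonding geometry.

    Strand 0 runs along +x centered at the origin; each further strand is
    the calibrated rigid transform of its predecessor (a flip plus offset
    for antiparallel sheets, a pure offset for parallel). Returns one atom
    list per strand.
    """
    if n_strands < 2:
        raise ValueError("a sheet needs at least 2 strands")
    base = build_backbone([(_PHI_STRAND, _PSI_STRAND)] * n_res)
    base = _orient(base, np.zeros(3), np.array([1.0, 0.0, 0.0]))
    # canonicalize the roll about the strand axis (PCA leaves it free and it
    # drifts with strand length, which would break the hydrogen-bond register
    # of the calibrated inter-strand transform): bring the first carbonyl
    # oxygen's off-axis component onto +y
    ref = base[0]["O"] - base[0]["CA"]
    ref_yz = np.array([0.0, ref[1], ref[2]])
    if np.linalg.norm(ref_yz) > 1e-9:
        roll = _rotation_between(ref_yz / np.linalg.norm(ref_yz),
                                 np.array([0.0, 1.0, 0.0]))
        base = _transform(base, roll, np.zeros(3))
    # anchor a central residue (not the centroid) so the hydrogen-bond
    # register against the flipped neighbour is independent of strand parity
    anchor = base[n_res // 2]["CA"].copy()
    base = [{k: v - anchor for k, v in res.items()} for res in base]
    strands = [base]
    anti_flip = _rot_y(_SHEET_TWIST_DEG) @ np.diag([-1.0, 1.0, -1.0])
    for _ in range(1, n_strands):
        prev = strands[-1]
        if antiparallel:
            nxt = _transform(prev, anti_flip, _ANTI_OFFSET * (spacing / 4.5))
        else:
            nxt = _transform(prev, np.eye(3), _PARA_OFFSET * (spacing / 4.4))
        strands.append(nxt)
    return strands


def make_coil(n_res: int, rng: np.random.Generator,
              origin=(0.0, 0.0, 0.0)) -> list[dict[str, np.ndarray]]:
    """Irregular backbone fragment that assigns as 'other'.

    Torsions are drawn from broad polyproline-II/extended-adjacent ranges
    that support no helical or ladder hydrogen bonding.
    """
    torsions = [(float(rng.uniform(-110, -60)), float(rng.uniform(100, 170)))
                for _ in range(n_res)]
    atoms = build_backbone(torsions)
    ca = np.array([r["CA"] for r in atoms])
    centroid = ca.mean(axis=0)
    return [{k: v - centroid + np.asarray(origin, float) for k, v in res.items()}
            for res in atoms]


# ---------------------------------------------------------------------------
# Entry assembly and spectrum law


@dataclass
class SpectrumLaw:
    """Fixture law mapping secondary-structure fractions to a spectrum.

    Three fixed component curves (sums of Gaussians, loosely shaped like
    textbook helix / strand / coil CD bases: the helix-like curve has a
    positive lobe near 193 nm and negative lobes near 208/222 nm). The
    spectrum of an entry is (alpha*C_H + beta*C_E + other*C_O)/100 plus
    optional Gaussian noise. When ``architecture_term`` is nonzero a small
    architecture-dependent bump is added, so that topology/fold matching
    carries signal that secondary-structure content alone does not.
    """

    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    architecture_term: float = 0.0

    # (center nm, width nm, amplitude) per component
    _HELIX = ((193.0, 6.0, 11.0), (208.0, 6.5, -9.0), (222.0, 7.0, -8.5))
    _STRAND = ((196.0, 7.0, 6.0), (217.0, 8.0, -5.0))
    _OTHER = ((198.0, 7.0, -6.5), (222.0, 10.0, 0.8))
    _ARCH_BUMPS = {"helix_bundle": (205.0, 8.0), "beta_sandwich": (214.0, 8.0),
                   "alpha_beta": (210.0, 8.0), "coil": (200.0, 8.0)}

    def _curve(self, gaussians) -> np.ndarray:
        wl = self.grid.wavelengths()
        out = np.zeros_like(wl)
        for center, width, amp in gaussians:
            out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
        return out

    def components(self) -> dict[str, np.ndarray]:
        return {"H": self._curve(self._HELIX), "E": self._curve(self._STRAND),
                "O": self._curve(self._OTHER)}

    def spectrum(self, alpha: float, beta: float, other: float,
                 architecture: str = "coil", noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 id: str = "") -> Spectrum:
        if abs(alpha + beta + other - 100.0) > 1e-6:
            raise ValueError("fractions must sum to 100")
        comp = self.components()
        vals = (alpha * comp["H"] + beta * comp["E"] + other * comp["O"]) / 100.0
        if self.architecture_term:
            center, width = self._ARCH_BUMPS[architecture]
            wl = self.grid.wavelengths()
            vals = vals + self.architecture_term * np.exp(
                -0.5 * ((wl - center) / width) ** 2)
        if noise_sd > 0:
            if rng is None:
                raise ValueError("noise requires an RNG")
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        return Spectrum(grid=self.grid, values=vals, id=id)


@dataclass
class SynthSpec:
    """Recipe for a synthetic basis set."""

    n_entries: int
    mixes: list[tuple[float, float, float]]          # target (alpha, beta, other) %
    architectures: list[str]
    noise_sd: float = 0.0
    seed: int = 0
    n_res: int = 140
    architecture_term: float = 0.0

    def __post_init__(self) -> None:
        if len(self.mixes) != self.n_entries or len(self.architectures) != self.n_entries:
            raise ValueError("mixes/architectures must match n_entries")
        for mix in self.mixes:
            if abs(sum(mix) - 100.0) > 1e-6:
                raise ValueError(f"mix {mix} does not sum to 100")


def fragments_to_structure(fragments, kinds=None, gap: int = 10,
                           chain_id: str = "A", struct_id: str = "synth"
                           ) -> tuple[ProteinStructure, list]:
    """Assemble atom-dict fragments into a one-chain structure.

    Sequence numbering jumps by ``gap`` between fragments so that each
    fragment is its own chain segment (no spurious secondary structure
    across the joins). Returns the structure and, when ``kinds`` is given,
    (chain_id, start, end, kind) header ranges for helix/strand fragments.
    """
    residues, ranges = [], []
    pos = 1
    for idx, frag in enumerate(fragments):
        start = pos
        for res in frag:
            residues.append(Residue(name="ALA", seq_pos=pos, atoms=dict(res)))
            pos += 1
        if kinds is not None and kinds[idx] in ("helix", "strand"):
            ranges.append((chain_id, start, pos - 1, kinds[idx]))
        pos += gap
    st = ProteinStructure(id=struct_id,
                          chains=[Chain(chain_id=chain_id, residues=residues)])
    return st, ranges


#: Fixed helix slot layout shared by every generated entry: a ring of up to
#: six antiparallel-neighbour axes. Entries differing only in content are
#: sub/super-structures of each other, so fold similarity tracks content
#: similarity instead of layout accidents.
_N_SLOTS = 8
_SLOT_RADIUS = 6.5
#: Outward lean per slot (degrees). Distinct tilts keep every helix-pair
#: angle away from the 0/180-degree histogram bin boundaries that an
#: idealized straight-up bundle would sit on exactly.
_SLOT_TILTS = (8.0, 11.0, 14.0, 17.0, 20.0, 23.0, 26.0, 29.0)


def _bundle_positions():
    out = []
    for i in range(_N_SLOTS):
        theta = 2.0 * np.pi * i / _N_SLOTS
        outward = np.array([np.cos(theta), np.sin(theta), 0.0])
        origin = _SLOT_RADIUS * outward
        tilt = np.deg2rad(_SLOT_TILTS[i])
        up = 1.0 if i % 2 == 0 else -1.0
        axis = np.cos(tilt) * np.array([0.0, 0.0, up]) + np.sin(tilt) * outward
        out.append((origin, axis))
    return out


#: Coil fragments use a fixed torsion stream so equal-sized coils are
#: identical across entries (per-entry randomness belongs to spectral noise).
_COIL_SEED = 20601
#: Vertical separation between the bundle, sheet and coil components (A).
_COMPONENT_SEP = 60.0
#: Lateral component drift per content percentage point (A).
_DRIFT_PER_POINT = 0.12


def _next_budget(tried: dict[int, float], target: float, current: int,
                 cap: int) -> int:
    """Propose the next residue budget for one content axis.

    With achieved values both below and above the target on record, bisect
    between the closest bracketing budgets; otherwise scale the current
    budget by the target/achieved ratio.
    """
    if target <= 0:
        return current
    below = [(n, got) for n, got in tried.items() if got < target]
    above = [(n, got) for n, got in tried.items() if got > target]
    if below and above:
        lo = max(n for n, _ in below)
        hi = min(n for n, _ in above)
        if hi - lo > 1:
            return (lo + hi) // 2
        # plateau edge: nudge outward from the closer side
        return lo if target - tried[lo] <= tried[hi] - target else hi
    got = tried[current]
    if got <= 0:
        return min(current + 6, cap)
    return int(np.clip(round(current * target / got), 4, cap))


def build_architecture(alpha: float, beta: float, other: float,
                       architecture: str, n_res: int,
                       rng: np.random.Generator):
    """Compose helix/sheet/coil fragments hitting the target content mix.

    Helix and strand ends lose their labels under the hydrogen-bond
    assigner, so fragment sizes are adjusted in a short fixed-point loop
    until the assigned percentages land within +/-5 points of the target
    (usually much closer). Returns (structure, header ranges, achieved mix)
    where the achieved mix is the assigner's (alpha, beta, other) for the
    built structure — the exact coordinates the spectrum law should use so
    that the synthetic spectrum is a true function of the structure.
    """
    if architecture == "helix_bundle" and beta > 40:
        raise ValueError("helix_bundle cannot reach high strand content")
    if architecture == "beta_sandwich" and alpha > 40:
        raise ValueError("beta_sandwich cannot reach high helix content")
    if architecture == "coil" and (alpha > 15 or beta > 15):
        raise ValueError("coil architecture is mostly 'other'")

    slots = _bundle_positions()
    n_h = int(round(alpha / 100.0 * n_res))
    n_e = int(round(beta / 100.0 * n_res))
    # component anchors drift smoothly with content, so whole-fold
    # structural similarity between entries decreases with content distance
    # in BOTH directions (surplus structure in either partner costs overlap)
    bundle_shift = np.array([_DRIFT_PER_POINT * (alpha - 40.0), 0.0, 0.0])
    sheet_shift = np.array([_DRIFT_PER_POINT * (beta - 30.0), 0.0, -_COMPONENT_SEP])
    coil_shift = np.array([_DRIFT_PER_POINT * (other - 45.0), 0.0, _COMPONENT_SEP])
    best = None
    tried_h: dict[int, float] = {}     # n_h -> achieved alpha %
    tried_e: dict[int, float] = {}
    seen: set[tuple[int, int]] = set()
    for _ in range(16):
        fragments, kinds = [], []
        # helices fill the fixed ring slots; lengths carry the content signal
        if n_h >= 6:
            n_units = int(np.clip(round(n_h / 12.0), 1, _N_SLOTS))
            per = max(6, int(round(n_h / n_units)))
            for u in range(n_units):
                origin, axis = slots[u]
                fragments.append(make_helix(per, origin=origin + bundle_shift,
                                            axis=axis))
                kinds.append("helix")
        # strands: one antiparallel sheet displaced from the bundle; strand
        # length capped at 10 (the inter-strand twist strains the register
        # of longer strands), extra content goes into more strands
        if n_e >= 8:
            n_strands = int(np.clip(round(n_e / 7.0), 2, 12))
            per = int(np.clip(round(n_e / n_strands), 4, 10))
            sheet = make_sheet(n_strands, per, antiparallel=True)
            for s in sheet:
                fragments.append([{k: v + sheet_shift for k, v in r.items()}
                                  for r in s])
                kinds.append("strand")
        used = sum(len(f) for f in fragments)
        n_o = max(0, n_res - used)
        if n_o >= 4:
            coil_rng = np.random.default_rng(_COIL_SEED)
            fragments.append(make_coil(n_o, coil_rng, origin=coil_shift))
            kinds.append("coil")
        st, ranges = fragments_to_structure(fragments, kinds)
        ss = assign_ss(st)
        n = len(ss)
        got_a = 100.0 * ss.count("H") / n
        got_b = 100.0 * ss.count("E") / n
        achieved = (got_a, got_b, 100.0 - got_a - got_b)
        miss = max(abs(got_a - alpha), abs(got_b - beta))
        if best is None or miss < best[0]:
            best = (miss, st, ranges, achieved)
        if miss <= 2.0:
            return st, ranges, achieved
        # compensate label loss at fragment ends; the achieved content is a
        # stepwise function of the residue budgets, so once a bracket exists
        # bisect instead of rescaling (a pure multiplicative update can
        # limit-cycle across a plateau)
        tried_h[n_h], tried_e[n_e] = got_a, got_b
        seen.add((n_h, n_e))
        n_h = _next_budget(tried_h, alpha, n_h, int(1.3 * n_res))
        n_e = _next_budget(tried_e, beta, n_e, int(1.6 * n_res))
        if (n_h, n_e) in seen:
            break
    if best[0] <= 5.0:
        return best[1], best[2], best[3]
    raise ValueError(
        f"could not hit mix ({alpha}, {beta}, {other}) with {architecture}")


# ---------------------------------------------------------------------------
# PDB output

_HELIX_CLASS = {"helix": 1, "helix310": 5}


def write_pdb(structure: ProteinStructure, path: str | Path,
              ss_ranges=()) -> None:
    """Write a single-model PDB file with optional HELIX/SHEET header records."""
    path = Path(path)
    lines = []
    helix_n = sheet_n = 0
    for chain_id, start, end, kind in ss_ranges:
        if kind in _HELIX_CLASS:
            helix_n += 1
            lines.append(
                f"HELIX  {helix_n:>3} {helix_n:>3} ALA {chain_id:1}{start:>5} "
                f"ALA {chain_id:1}{end:>5} {_HELIX_CLASS[kind]:>2}"
                f"{'':30}{end - start + 1:>6}")
        elif kind == "strand":
            sheet_n += 1
            lines.append(
                f"SHEET  {sheet_n:>3} S{1:>2}{1:>2} ALA {chain_id:1}{start:>4}  "
                f"ALA {chain_id:1}{end:>4}  0")
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for name in ("N", "CA", "C", "O"):
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:>5} {name:^4} {res.name:>3} {chain.chain_id:1}"
                    f"{res.seq_pos:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}{'':10}{element:>2}")
                serial += 1
        last = chain.residues[-1]
        lines.append(f"TER   {serial:>5}       {last.name:>3} "
                     f"{chain.chain_id:1}{last.seq_pos:>4}")
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def make_entry(mix: tuple[float, float, float], architecture: str,
               out_prefix: str | Path, law: SpectrumLaw,
               rng: np.random.Generator, noise_sd: float = 0.0,
               n_res: int = 140) -> tuple[Path, Path]:
    """Build one synthetic (PDB file, spectrum file) pair.

    The structure hits the target mix within +/-5 percentage points as seen
    by the hydrogen-bond assigner; the spectrum follows the law evaluated at
    the achieved content. Returns the two file paths.
    """
    alpha, beta, other = mix
    st, ranges, achieved = build_architecture(alpha, beta, other, architecture,
                                              n_res, rng)
    prefix = Path(out_prefix)
    pdb_path = prefix.with_suffix(".pdb")
    spec_path = prefix.with_suffix(".txt")
    write_pdb(st, pdb_path, ss_ranges=ranges)
    # the law sees the achieved content, so spectrum is an exact function of
    # the structure as the assigner measures it
    spectrum = law.spectrum(*achieved, architecture=architecture,
                            noise_sd=noise_sd, rng=rng, id=prefix.stem)
    write_spectrum(spectrum, spec_path)
    return pdb_path, spec_path


def default_mixes(n_entries: int) -> list[tuple[tuple[float, float, float], str]]:
    """A lattice of content mixes spanning the alpha/beta plane.

    Alternates helix-rich, strand-rich and mixed entries so that a basis of
    ~20 covers the region queries are drawn from.
    """
    mixes: list[tuple[tuple[float, float, float], str]] = []
    alphas = np.linspace(5.0, 75.0, max(2, int(np.ceil(n_entries / 3))))
    for a in alphas:
        for b_frac in (0.1, 0.45, 0.8):
            b = float(round(min(b_frac * (90.0 - a), 55.0), 1))
            a_r = float(round(a, 1))
            o = float(round(100.0 - a_r - b, 1))
            if o < 5:
                continue
            arch = ("helix_bundle" if a_r >= 2 * b else
                    "beta_sandwich" if b >= 2 * a_r else "alpha_beta")
            if a_r < 10 and b < 10:
                arch = "coil"
            mixes.append(((a_r, b, o), arch))
    return mixes[:n_entries]


def make_basis(spec: SynthSpec, outdir: str | Path) -> Path:
    """Write a full synthetic basis (PDB + spectrum per entry) and manifest.

    Deterministic for a fixed spec: the same seed yields identical files.
    Returns the manifest path, ready for :func:`structcd.basis.build_basis`.
    """
    if spec.n_entries < 4:
        raise ValueError("a basis needs at least 4 entries")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    law = SpectrumLaw(architecture_term=spec.architecture_term)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i, (mix, arch) in enumerate(zip(spec.mixes, spec.architectures)):
        entry_id = f"syn{i:03d}"
        pdb_path, spec_path = make_entry(
            mix, arch, outdir / entry_id, law, rng,
            noise_sd=spec.noise_sd, n_res=spec.n_res)
        rows.append((entry_id, pdb_path.name, spec_path.name))
    manifest = outdir / "manifest.tsv"
    with manifest.open("w") as fh:
        for entry_id, pdb_name, spec_name in rows:
            fh.write(f"{entry_id}\t{pdb_name}\t{spec_name}\n")
    return manifest
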