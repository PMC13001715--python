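"""Synthetic fixtures for the whole pipeline.

Everything here is a pure function of (spec, seed): a toy albumin-like
six-site Cu(II) decoy structure whose constrained Cu-Cu separations honour
the experimentally anchored envelopes, CW pseudo-titration spectra with a
saturating high-affinity species, ESEEM/HYSCORE time traces, and RIDME
dipolar traces.  The decoy is *synthetic*: donor residue names and numbers
are those of the real albumin sites so canonical labelling works, but the
geometry is an embedding of the target distances, not a protein fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from cuepr.cw import CWSpectrum, SpectrometerSettings, SpinSystem, double_integral, powder_spectrum, superpose
from cuepr.hyperfine import DEFAULT_NQI_LINES, EseemTrace, HyscoreData, simulate_nqi_eseem
from cuepr.occupancy import DistanceDistribution, OccupancyConfig, default_r_grid, simulate_distribution
from cuepr.ridme import BackgroundModel, RidmeTrace, simulate_ridme
from cuepr.structure import Atom, DistanceTable, Structure

__all__ = [
    "DecoySpec",
    "NoiseSpec",
    "SITE_ORDER",
    "make_decoy_structure",
    "make_cw_titration",
    "make_eseem_fixture",
    "make_hyscore_fixture",
    "make_ridme_fixture",
    "make_fixture_set",
    "simulate_hyscore_tones",
    "default_spin_systems",
]

#: Canonical site order (by first donor residue number: 1, 9, 67, 152, 211, 509).
SITE_ORDER = ("ATCUN", "siteB", "siteA", "H287", "H317", "H509")

# Donor shells written for each site: (residue name, residue number, atom
# name, element).  Waters at site A reflect its partly solvent-completed
# coordination sphere.
_SITE_DONORS: dict[str, list[tuple[str, int, str, str]]] = {
    "ATCUN": [("ASP", 1, "N", "N"), ("THR", 2, "N", "N"), ("HIS", 3, "NE2", "N")],
    "siteB": [("HIS", 9, "NE2", "N"), ("ASP", 13, "OD1", "O")],
    "siteA": [
        ("HIS", 67, "NE2", "N"),
        ("HIS", 246, "NE2", "N"),
        ("ASP", 248, "OD1", "O"),
        ("HOH", 701, "O", "O"),
    ],
    "H287": [("GLU", 152, "OE1", "O"), ("HIS", 287, "NE2", "N")],
    "H317": [("ASP", 211, "OD1", "O"), ("HIS", 317, "NE2", "N")],
    "H509": [("HIS", 509, "NE2", "N"), ("GLU", 564, "OE1", "O")],
}


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level as a fraction of the maximum amplitude."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass
class DecoySpec:
    """Target Cu-Cu distances (nm) for the constrained pairs of the decoy.

    Fixed anchors: ATCUN-siteB on the short edge (1.8 nm) and ATCUN-H287 at
    3.5 nm.  Range-constrained pairs (H317 to ATCUN/siteA/siteB/H287 within
    4.0-4.9 nm; H509 to everything within 4.5-7.6 nm) get seeded draws from
    the interior of their envelopes.  Remaining pairs are left to the
    embedder.
    """

    seed: int = 0
    atcun_siteb: float = 1.8
    atcun_h287: float = 3.5
    h317_range: tuple[float, float] = (4.0, 4.9)
    h509_range: tuple[float, float] = (4.5, 7.6)
    constrained: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.constrained:
            rng = np.random.default_rng(self.seed)
            c: dict[tuple[str, str], float] = {
                ("ATCUN", "siteB"): self.atcun_siteb,
                ("ATCUN", "H287"): self.atcun_h287,
            }
            lo, hi = self.h317_range
            for other in ("ATCUN", "siteA", "siteB", "H287"):
                c[tuple(sorted((other, "H317")))] = float(
                    rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
                )
            lo, hi = self.h509_range
            for other in ("ATCUN", "siteA", "siteB", "H287", "H317"):
                c[tuple(sorted((other, "H509")))] = float(
                    rng.uniform(lo + 0.1 * (hi - lo), lo + 0.6 * (hi - lo))
                )
            self.constrained = {tuple(sorted(k)): v for k, v in c.items()}


# soft initial guesses (nm) for the pairs the embedder is free to place
_FREE_PAIR_HINTS: dict[tuple[str, str], float] = {
    ("ATCUN", "siteA"): 2.0,
    ("siteA", "siteB"): 2.2,
    ("H287", "siteA"): 3.0,
    ("H287", "siteB"): 3.3,
}


def _embed_sites(spec: DecoySpec) -> np.ndarray:
    """3-D coordinates (nm) for the six Cu sites realising the constraints.

    Classical multidimensional scaling on the full (anchor + hint) matrix
    provides the start; bounded least squares then drives the constrained
    pair residuals below 1e-6 while free pairs absorb the slack.
    """
    labels = list(SITE_ORDER)
    n = len(labels)
    target = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((labels[i], labels[j])))
            d = spec.constrained.get(key, _FREE_PAIR_HINTS.get(key, 3.0))
            target[i, j] = target[j, i] = d

    # classical MDS initialisation
    d2 = target**2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j_mat @ d2 @ j_mat
    evals, evecs = np.linalg.eigh(gram)
    idx = np.argsort(evals)[::-1][:3]
    x0 = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0.0, None))

    pairs = [
        (labels.index(a), labels.index(b))
        for (a, b) in spec.constrained
    ]
    targets = np.array([spec.constrained[k] for k in spec.constrained])

    def resid(flat: np.ndarray) -> np.ndarray:
        xyz = flat.reshape(n, 3)
        d = np.array([np.linalg.norm(xyz[i] - xyz[j]) for i, j in pairs])
        return d - targets

    rng = np.random.default_rng(spec.seed)
    best = None
    for attempt in range(8):
        start = x0.ravel() if attempt == 0 else (
            x0.ravel() + rng.normal(0.0, 0.3, size=3 * n)
        )
        sol = least_squares(resid, start, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        err = float(np.max(np.abs(resid(sol.x))))
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err < 1e-8:
            break
    err, flat = best
    if err > 1e-6:
        report = "\n".join(
            f"  {labels[i]}-{labels[j]}: target {t:.3f} nm, "
            f"residual {r:+.2e} nm"
            for (i, j), t, r in zip(pairs, targets, resid(flat))
        )
        raise ValueError(
            f"distance constraints not satisfiable in 3-D "
            f"(max residual {err:.2e} nm):\n{report}"
        )
    return flat.reshape(n, 3)


def _donor_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """n roughly orthogonal unit vectors with a seeded random orientation."""
    basis = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    # random rotation from a QR decomposition
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return basis[:n] @ q.T


def make_decoy_structure(
    spec: DecoySpec | None = None, path: str | Path | None = None
) -> Structure:
    """Six-Cu decoy structure honouring the anchored distance envelopes.

    Each Cu carries 2-4 donor atoms (His NE2 / Asp OD1-style, canonical
    residue numbers) at 2.0-2.3 A.  The file is written as P1 with a box
    enclosing all atoms plus 20 A of padding.  Identical (spec, seed) give
    byte-identical files.
    """
    spec = spec or DecoySpec()
    xyz_nm = _embed_sites(spec)
    xyz = xyz_nm * 10.0  # nm -> A
    rng = np.random.default_rng(spec.seed + 1)

    atoms: list[Atom] = []
    serial = 0
    for si, label in enumerate(SITE_ORDER):
        cu_pos = xyz[si]
        donors = _SITE_DONORS[label]
        directions = _donor_directions(rng, len(donors))
        for (resname, resnum, atname, element), direction in zip(donors, directions):
            serial += 1
            bond = float(rng.uniform(2.0, 2.3))
            pos = cu_pos + bond * direction
            atoms.append(
                Atom(
                    serial=serial,
                    name=atname,
                    element=element,
                    residue_name=resname,
                    residue_number=resnum,
                    chain_id="A",
                    position=tuple(np.round(pos, 3)),
                    occupancy=1.0,
                    b_factor=30.0,
                )
            )
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="CU",
                element="Cu",
                residue_name="CU",
                residue_number=601 + si,
                chain_id="A",
                position=tuple(np.round(cu_pos, 3)),
                occupancy=1.0,
                b_factor=40.0,
            )
        )

    coords = np.array([a.position for a in atoms])
    shift = 20.0 - coords.min(axis=0)
    atoms = [
        Atom(
            serial=a.serial,
            name=a.name,
            element=a.element,
            residue_name=a.residue_name,
            residue_number=a.residue_number,
            chain_id=a.chain_id,
            position=tuple(np.round(np.asarray(a.position) + shift, 3)),
            occupancy=a.occupancy,
            b_factor=a.b_factor,
        )
        for a in atoms
    ]
    coords = np.array([a.position for a in atoms])
    box = np.ceil(coords.max(axis=0) + 20.0)
    cell = (float(box[0]), float(box[1]), float(box[2]), 90.0, 90.0, 90.0)
    structure = Structure(
        atoms=atoms, unit_cell=cell, space_group="P 1", title="Cu6 decoy"
    )
    if path is not None:
        _write_pdb(structure, path)
    return structure


def _write_pdb(structure: Structure, path: str | Path) -> None:
    a, b, c, al, be, ga = structure.unit_cell
    lines = [
        f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} "
        f"{structure.space_group or 'P 1':<11s}{1:4d}"
    ]
    for at in structure.atoms:
        record = "HETATM" if at.residue_name in ("CU", "HOH") else "ATOM  "
        x, y, z = at.position
        name = at.name if len(at.name) == 4 else f" {at.name:<3s}"
        lines.append(
            f"{record}{at.serial:5d} {name}{'':1s}{at.residue_name:>3s} "
            f"{at.chain_id:1s}{at.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{at.occupancy:6.2f}{at.b_factor:6.2f}"
            f"{'':10s}{at.element.upper():>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CW titration


def default_spin_systems() -> list[SpinSystem]:
    """Two representative axial Cu(II) species.

    The high-affinity N-terminal (ATCUN-like) species uses the published
    axial parameters g_par = 2.198, A_par = 607 MHz; its perpendicular
    components and the secondary-site parameters are representative values
    for N/O-coordinated Cu(II) and are meant to be replaced by fitted
    numbers when available.
    """
    return [
        SpinSystem(g_par=2.198, g_perp=2.05, a_par=607.0, a_perp=60.0,
                   gauss_fwhm=25.0, label="ATCUN"),
        SpinSystem(g_par=2.28, g_perp=2.06, a_par=480.0, a_perp=40.0,
                   gauss_fwhm=35.0, label="secondary"),
    ]


def make_cw_titration(
    equivalents: list[float],
    systems: list[SpinSystem] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    settings: SpectrometerSettings | None = None,
    n_orientations: int = 201,
) -> list[CWSpectrum]:
    """Pseudo-titration CW series with a saturating high-affinity species.

    Species weights at e molar equivalents: the first (high-affinity,
    ATCUN-like) species takes min(e, 1) and the remainder goes to the
    other species, so the summed double integral is proportional to e while
    the ATCUN weight stops growing beyond 1 equivalent.  Species spectra are
    normalized to unit double integral before weighting.
    """
    systems = systems or default_spin_systems()
    settings = settings or SpectrometerSettings()
    base = []
    for sys in systems:
        sp = powder_spectrum(sys, settings, n_orientations=n_orientations)
        di = double_integral(sp)
        base.append(CWSpectrum(sp.field, sp.intensity / di,
                               provenance={"system": sys.label}))

    rng = np.random.default_rng(noise.seed)
    out = []
    max_amp = 0.0
    noiseless = []
    for eq in equivalents:
        w_first = min(eq, 1.0)
        rest = max(eq - w_first, 0.0)
        weights = [w_first] + [rest / max(len(base) - 1, 1)] * (len(base) - 1)
        sp = superpose(base, weights)
        noiseless.append(sp)
        max_amp = max(max_amp, float(np.max(np.abs(sp.intensity))))
    for sp in noiseless:
        intensity = sp.intensity
        if noise.sigma > 0:
            intensity = intensity + rng.normal(
                0.0, noise.sigma * max_amp, size=intensity.shape
            )
        out.append(CWSpectrum(sp.field, intensity, provenance=sp.provenance))
    return out


# ---------------------------------------------------------------------------
# trace fixtures


def simulate_hyscore_tones(
    nu1: float = 4.0,
    nu2: float = 7.0,
    n: int = 64,
    dwell: float = 16.0,
    t_start: float = 56.0,
    decay_tau: float = 3000.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    tau: float = 292.0,
) -> HyscoreData:
    """Separable two-tone HYSCORE matrix: cos(2 pi nu1 t1) cos(2 pi nu2 t2)
    on a decaying baseline, for exercising the 2-D processing chain."""
    t1 = t_start + dwell * np.arange(n)
    t2 = t_start + dwell * np.arange(n)
    decay = np.exp(-t1 / decay_tau)[:, None] * np.exp(-t2 / decay_tau)[None, :]
    osc = np.cos(2 * np.pi * nu1 * 1e-3 * t1)[:, None] * np.cos(
        2 * np.pi * nu2 * 1e-3 * t2
    )[None, :]
    matrix = decay * (1.0 + 0.3 * osc)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        matrix = matrix + rng.normal(0.0, noise_sigma, size=matrix.shape)
    return HyscoreData(t1_axis=t1, t2_axis=t2, matrix=matrix, tau=tau)


def make_eseem_fixture(
    path: str | Path,
    lines: tuple[tuple[float, float], ...] = DEFAULT_NQI_LINES,
    noise: NoiseSpec = NoiseSpec(sigma=0.002),
    tau: float = 292.0,
    apply_blind_spots: bool = False,
) -> EseemTrace:
    trace = simulate_nqi_eseem(
        lines=lines, noise_sigma=noise.sigma, seed=noise.seed, tau=tau,
        apply_blind_spots=apply_blind_spots,
    )
    trace.to_text(path)
    return trace


def make_hyscore_fixture(
    path: str | Path,
    nu1: float = 4.0,
    nu2: float = 7.0,
    noise: NoiseSpec = NoiseSpec(sigma=0.002),
) -> HyscoreData:
    data = simulate_hyscore_tones(
        nu1=nu1, nu2=nu2, noise_sigma=noise.sigma, seed=noise.seed
    )
    data.to_text(path)
    return data


def make_ridme_fixture(
    path: str | Path,
    table: DistanceTable,
    config: OccupancyConfig,
    background: BackgroundModel = BackgroundModel(),
    sigma: float = 0.1,
    noise: NoiseSpec = NoiseSpec(sigma=0.01),
) -> RidmeTrace:
    """RIDME trace for an occupancy configuration of the decoy table."""
    dist = simulate_distribution(config, table, sigma=sigma,
                                 r_grid=default_r_grid(1.0, 10.0, 0.02))
    trace = simulate_ridme(
        dist, background, noise_sigma=noise.sigma, seed=noise.seed
    )
    trace.to_text(path)
    return trace


def make_fixture_set(outdir: str | Path, seed: int = 0) -> dict[str, dict]:
    """Write the full fixture tree (decoy + traces) with a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    decoy_path = outdir / "decoy.pdb"
    structure = make_decoy_structure(DecoySpec(seed=seed), path=decoy_path)
    manifest["decoy.pdb"] = {"seed": seed, "kind": "structure",
                             "n_atoms": len(structure.atoms)}

    from cuepr.structure import detect_metal_sites, pairwise_distances

    sites = detect_metal_sites(structure)
    table = pairwise_distances(sites)
    table_path = outdir / "distances.tsv"
    table.to_tsv(table_path)
    manifest["distances.tsv"] = {"seed": seed, "kind": "distance_table"}

    make_eseem_fixture(outdir / "eseem.txt", noise=NoiseSpec(0.002, seed))
    manifest["eseem.txt"] = {"seed": seed, "kind": "eseem_trace"}

    make_hyscore_fixture(outdir / "hyscore.txt", noise=NoiseSpec(0.002, seed))
    manifest["hyscore.txt"] = {"seed": seed, "kind": "hyscore_matrix"}

    config = OccupancyConfig.of("ATCUN", "siteB", "H287")
    make_ridme_fixture(outdir / "ridme.txt", table, config,
                       noise=NoiseSpec(0.01, seed))
    manifest["ridme.txt"] = {"seed": seed, "kind": "ridme_trace",
                             "config": str(config)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest
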