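"""Register scanning of a TF probe along nucleosomal DNA and interface areas.

A TF-DNA co-crystal "probe" is superposed, via its DNA backbone anchor
atoms, onto every 1-bp register of the nucleosomal DNA; the clash score at a
register is the number of TF protein atoms closer than a threshold (1 A
default) to any nucleosome atom. Buried interface areas between atom groups
are measured by numerical solvent-accessible surface area (Shrake-Rupley on
a deterministic golden-spiral point lattice):

    buried = (SASA(A) + SASA(B) - SASA(A u B)) / 2
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .nucframe import NucFrame, pos_to_shl
from .seenseq import EnrichmentProfile

__all__ = [
    "AtomModel",
    "ProbeModel",
    "ClashProfile",
    "VDW_RADII",
    "superpose",
    "clash_scan",
    "interface_area",
    "overlay_profiles",
    "read_structure",
    "write_pdb",
]

logger = logging.getLogger(__name__)

#: Van der Waals radii in Angstrom (Bondi set, common elements).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "MG": 1.73, "MN": 1.73,
    "ZN": 1.39, "FE": 1.40, "NA": 2.27, "K": 2.75, "CA": 2.31,
}
DEFAULT_RADIUS = 1.70


@dataclass
class AtomModel:
    """A flat atomic model partitioned into named groups.

    ``atoms`` is a DataFrame with columns: element, name, chain, resid,
    resname, x, y, z, group. Every atom belongs to exactly one group
    (e.g. tf-protein, probe-dna, nucleosome-histone, nucleosome-dna).
    """

    atoms: pd.DataFrame

    REQUIRED = ("element", "name", "chain", "resid", "resname", "x", "y", "z", "group")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"atom table missing columns: {sorted(missing)}")
        xyz = self.coords()
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    def coords(self, group: str | None = None) -> np.ndarray:
        df = self.atoms if group is None else self.atoms[self.atoms["group"] == group]
        return df[["x", "y", "z"]].to_numpy(float)

    def select(self, group: str) -> pd.DataFrame:
        return self.atoms[self.atoms["group"] == group]

    def groups(self) -> list[str]:
        return sorted(self.atoms["group"].unique())

    def radii(self, group: str | None = None, fallback: float = DEFAULT_RADIUS) -> np.ndarray:
        df = self.atoms if group is None else self.select(group)
        rad = np.empty(len(df))
        unknown: set[str] = set()
        for i, el in enumerate(df["element"].str.upper()):
            r = VDW_RADII.get(el)
            if r is None:
                unknown.add(el)
                r = fallback
            rad[i] = r
        if unknown:
            warnings.warn(
                f"unknown element radii for {sorted(unknown)}; using fallback {fallback} A",
                stacklevel=2,
            )
        return rad

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomModel":
        out = self.atoms.copy()
        out[["x", "y", "z"]] = self.coords() @ rotation.T + translation
        return AtomModel(out)


@dataclass
class ProbeModel:
    """A TF-DNA probe with per-base-pair DNA anchor atoms (both strands).

    ``anchors`` has shape (n_bp, 2, 3): for each probe base pair, the anchor
    atom coordinate (P, or C1' fallback) on each strand.
    """

    model: AtomModel
    anchors: np.ndarray

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, float)
        if self.anchors.ndim != 3 or self.anchors.shape[1:] != (2, 3):
            raise ValueError("anchors must have shape (n_bp, 2, 3)")

    @property
    def n_bp(self) -> int:
        return self.anchors.shape[0]


@dataclass
class ClashProfile:
    """Per-register clash counts and superposition RMSDs."""

    registers: np.ndarray
    counts: np.ndarray
    rmsd: np.ndarray
    threshold_A: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"register": self.registers, "rmsd": self.rmsd, "clash_count": self.counts}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def superpose(probe_anchors: np.ndarray, target_anchors: np.ndarray):
    """Least-squares rigid-body superposition (Kabsch, no reflection).

    Returns ``(rotation, translation, rmsd)`` such that
    ``probe @ rotation.T + translation`` best fits the target.
    """
    P = np.asarray(probe_anchors, float).reshape(-1, 3)
    T = np.asarray(target_anchors, float).reshape(-1, 3)
    if P.shape != T.shape or len(P) < 3:
        raise ValueError("need >= 3 paired anchors of equal count")
    pc, tc = P.mean(0), T.mean(0)
    P0, T0 = P - pc, T - tc
    # collinearity check: rank of the centred anchor cloud
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(T0, tol=1e-8) < 2:
        raise ValueError("degenerate geometry: anchors are collinear")
    H = P0.T @ T0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - T) ** 2, axis=1))))
    return R, t, rmsd


def clash_scan(
    probe: ProbeModel,
    nucleosome: AtomModel,
    nuc_anchors: np.ndarray,
    threshold_A: float = 1.0,
    step_bp: int = 1,
    window_bp: int | None = None,
    tf_group: str = "tf-protein",
) -> ClashProfile:
    """Scan the probe along every register of the nucleosomal DNA.

    For each register r (0-based bp offset, every ``step_bp``), the probe DNA
    anchors over a ``window_bp`` window are superposed onto the nucleosomal
    anchors at [r, r + window_bp); the probe's TF protein atoms are
    transformed and those within ``threshold_A`` of ANY nucleosome atom
    (histones and DNA alike) are counted. The KD-tree count equals
    brute-force all-pairs counting exactly.
    """
    nuc_anchors = np.asarray(nuc_anchors, float)
    if nuc_anchors.ndim != 3 or nuc_anchors.shape[1:] != (2, 3):
        raise ValueError("nuc_anchors must have shape (n_bp, 2, 3)")
    window = probe.n_bp if window_bp is None else int(window_bp)
    if window > probe.n_bp:
        raise ValueError("window_bp exceeds probe DNA length")
    n_nuc_bp = nuc_anchors.shape[0]
    if window > n_nuc_bp:
        raise ValueError("window_bp exceeds nucleosomal DNA length")
    # probe anchors: centre the window on the probe DNA
    off = (probe.n_bp - window) // 2
    p_anch = probe.anchors[off: off + window].reshape(-1, 3)

    tf_xyz = probe.model.coords(tf_group)
    nuc_tree = cKDTree(nucleosome.coords())

    regs, counts, rmsds = [], [], []
    for r in range(0, n_nuc_bp - window + 1, step_bp):
        t_anch = nuc_anchors[r: r + window].reshape(-1, 3)
        if not np.all(np.isfinite(t_anch)):
            warnings.warn(f"register {r}: missing anchors, skipped", stacklevel=2)
            continue
        R, t, rmsd = superpose(p_anch, t_anch)
        if len(tf_xyz):
            moved = tf_xyz @ R.T + t
            n_clash = int(np.sum(nuc_tree.query(moved, k=1)[0] < threshold_A))
        else:
            n_clash = 0
        regs.append(r)
        counts.append(n_clash)
        rmsds.append(rmsd)
    return ClashProfile(
        registers=np.array(regs), counts=np.array(counts), rmsd=np.array(rmsds),
        threshold_A=threshold_A,
    )


def _sphere_lattice(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.c_[np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius_A: float = 1.4,
    n_points: int = 960,
) -> float:
    """Total solvent-accessible surface area (A^2), Shrake-Rupley style.

    Each atom's expanded sphere (r + probe) is sampled on a fixed golden-
    spiral lattice; points inside any neighbouring expanded sphere are
    occluded. Deterministic for fixed ``n_points``.
    """
    coords = np.asarray(coords, float)
    R = np.asarray(radii, float) + probe_radius_A
    lattice = _sphere_lattice(n_points)
    tree = cKDTree(coords)
    total = 0.0
    rmax = R.max()
    for i in range(len(coords)):
        pts = coords[i] + R[i] * lattice
        nbrs = [j for j in tree.query_ball_point(coords[i], R[i] + rmax) if j != i]
        if nbrs:
            d = np.linalg.norm(pts[:, None, :] - coords[nbrs][None, :, :], axis=2)
            exposed = np.all(d >= R[nbrs][None, :], axis=1)
        else:
            exposed = np.ones(n_points, bool)
        total += 4.0 * np.pi * R[i] ** 2 * exposed.mean()
    return float(total)


def interface_area(
    model: AtomModel,
    group_a: str,
    group_b: str,
    probe_radius_A: float = 1.4,
    n_points: int = 960,
    fallback_radius_A: float = DEFAULT_RADIUS,
) -> float:
    """Buried interface area (A^2) between two atom groups.

    (SASA(a alone) + SASA(b alone) - SASA(a u b)) / 2, all computed with the
    same deterministic point lattice.
    """
    a, b = model.select(group_a), model.select(group_b)
    if a.empty or b.empty:
        raise ValueError(f"groups {group_a!r}/{group_b!r} must be non-empty")
    xa, xb = a[["x", "y", "z"]].to_numpy(float), b[["x", "y", "z"]].to_numpy(float)
    ra = model.radii(group_a, fallback=fallback_radius_A)
    rb = model.radii(group_b, fallback=fallback_radius_A)
    s_a = sasa(xa, ra, probe_radius_A, n_points)
    s_b = sasa(xb, rb, probe_radius_A, n_points)
    s_ab = sasa(np.vstack([xa, xb]), np.concatenate([ra, rb]), probe_radius_A, n_points)
    return max(0.0, (s_a + s_b - s_ab) / 2.0)


def overlay_profiles(
    clash: ClashProfile,
    profile: EnrichmentProfile,
    frame: NucFrame | None = None,
    register_offset: int = 0,
) -> pd.DataFrame:
    """Join a clash profile with a SeEN-seq enrichment profile by position.

    Registers map to tiling positions via ``position = register + offset``
    (identity under default frames). Adds a Spearman rank correlation between
    -clash and enrichment (NaN, flagged, when either side is constant).
    """
    frame = frame or NucFrame()
    ctab = clash.to_frame().rename(columns={"register": "position"})
    ctab["position"] = ctab["position"] + register_offset
    etab = profile.table[["position", "mean"]].rename(columns={"mean": "enrichment"})
    joined = ctab.merge(etab, on="position", how="inner")
    if joined.empty:
        raise ValueError("clash registers and enrichment positions have disjoint support")
    joined["shl"] = [
        pos_to_shl(frame, int(p)) if 0 <= p < frame.length_bp else np.nan
        for p in joined["position"]
    ]
    ok = joined["enrichment"].notna()
    if joined.loc[ok, "clash_count"].nunique() < 2 or joined.loc[ok, "enrichment"].nunique() < 2:
        rho = np.nan
        logger.warning("constant profile: clash/enrichment correlation undefined")
    else:
        rho = float(spearmanr(-joined.loc[ok, "clash_count"], joined.loc[ok, "enrichment"]).statistic)
    joined.attrs["spearman_neg_clash_vs_enrichment"] = rho
    return joined[["position", "shl", "enrichment", "clash_count", "rmsd"]]


def paired_anchors(
    model: AtomModel,
    chain_a: str,
    chain_b: str,
    atom_name: str = "P",
    fallback: str = "C1'",
) -> np.ndarray:
    """Per-base-pair anchor coordinates from a DNA duplex's two chains.

    Takes one ``atom_name`` atom (``fallback`` where absent) per residue per
    chain, ordered by residue number; the second strand is reversed so that
    antiparallel base pairs line up. Returns an (n_bp, 2, 3) array.
    """
    def _strand(chain: str) -> np.ndarray:
        sub = model.atoms[model.atoms["chain"] == chain]
        if sub.empty:
            raise ValueError(f"chain {chain!r} not found")
        pts = []
        for _, res in sub.groupby("resid", sort=True):
            hit = res[res["name"] == atom_name]
            if hit.empty:
                hit = res[res["name"] == fallback]
            if hit.empty:
                pts.append([np.nan] * 3)
            else:
                pts.append(hit.iloc[0][["x", "y", "z"]].tolist())
        return np.asarray(pts, float)

    a, b = _strand(chain_a), _strand(chain_b)[::-1]
    n = min(len(a), len(b))
    return np.stack([a[:n], b[:n]], axis=1)


# ---------------------------------------------------------------------------
# PDB / mmCIF I/O (gemmi-backed)

def read_structure(path, group_map: dict[str, str] | None = None, default_group: str = "ungrouped") -> AtomModel:
    """Read a PDB or mmCIF file into an AtomModel.

    ``group_map`` maps chain ids to group labels; unmapped chains get
    ``default_group``. Altlocs: the highest-occupancy conformer is kept.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    rows = []
    gm = group_map or {}
    for mod in st:
        for chain in mod:
            grp = gm.get(chain.name, default_group)
            for res in chain:
                for atom in res:
                    rows.append(
                        (atom.element.name.upper(), atom.name, chain.name,
                         res.seqid.num, res.name,
                         atom.pos.x, atom.pos.y, atom.pos.z, grp)
                    )
        break  # first model only
    return AtomModel(pd.DataFrame(rows, columns=list(AtomModel.REQUIRED)))


def write_pdb(model: AtomModel, path) -> None:
    """Write an AtomModel as a minimal single-model PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = "nucaccess"
    md = gemmi.Model("1")
    for chain_id, sub in model.atoms.groupby("chain", sort=False):
        ch = gemmi.Chain(str(chain_id))
        for resid, res_df in sub.groupby("resid", sort=False):
            res = gemmi.Residue()
            res.name = str(res_df["resname"].iloc[0])
            res.seqid = gemmi.SeqId(int(resid), " ")
            for _, row in res_df.iterrows():
                at = gemmi.Atom()
                at.name = str(row["name"])
                at.element = gemmi.Element(str(row["element"]))
                at.pos = gemmi.Position(row["x"], row["y"], row["z"])
                at.occ = 1.0
                res.add_atom(at)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
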