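"""File formats: SDF V2000 conformers with a pharmacophore-feature data
tag, assay outcome CSV, and the TSV layouts for scores, descriptors and
statistics reports.

All writers are deterministic (sorted keys, fixed decimal formatting) so
identical runs produce byte-identical files.  Scores are serialized at 4
decimal places, transforms at 6; the stored ComboT columns are the exact
sums of the stored (rounded) ST and CT columns so files are internally
consistent.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

from .align import MEASURES, SimilarityRecord
from .assays import AssayTable, ASSAY_CATEGORIES, Histogram, MeasureStats, PerAidStats
from .molecules import Atom, Conformer, DescriptorSet, FeaturePoint, FEATURE_TYPES
from .transforms import RigidTransform

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: SDF data item holding the feature list.  Line 1 is the feature count;
#: each following line is "k a1 ... ak type" with k member-atom count and
#: 1-based indices over the record's heavy atoms.
FEATURE_TAG = "PHARMACOPHORE_FEATURES"

_TYPE_TO_TAG = {t: ("rings" if t == "ring" else t) for t in FEATURE_TYPES}
_TAG_TO_TYPE = {v: k for k, v in _TYPE_TO_TAG.items()}

STAT_FIELDS = ("mu_nn", "sd_nn", "mu_ni", "sd_ni", "mu_diff", "sd_diff")


# ---------------------------------------------------------------------------
# SDF


def _feature_block(conf: Conformer) -> str:
    lines = [str(len(conf.features))]
    for f in conf.features:
        members = " ".join(str(i) for i in f.member_atoms)
        lines.append(f"{len(f.member_atoms)} {members} {_TYPE_TO_TAG[f.ftype]}")
    return "\n".join(lines)


def write_sdf(conformers: Iterable[Conformer], path: str | Path) -> None:
    """Write heavy-atom-only V2000 records (no bonds) plus the feature tag."""
    writer = Chem.SDWriter(str(path))
    try:
        for conf in conformers:
            mol = Chem.RWMol()
            rd_conf = Chem.Conformer(conf.n_atoms)
            for i, atom in enumerate(conf.atoms):
                mol.AddAtom(Chem.Atom(atom.element))
                rd_conf.SetAtomPosition(i, Point3D(*atom.position))
            mol.AddConformer(rd_conf)
            mol.SetProp("_Name", str(conf.cid))
            mol.SetProp(FEATURE_TAG, _feature_block(conf))
            mol.UpdatePropertyCache(strict=False)
            writer.write(mol)
    finally:
        writer.close()


def _parse_features(block: str, atoms: list[Atom]) -> list[FeaturePoint]:
    lines = [ln for ln in block.strip().splitlines() if ln.strip()]
    if not lines:
        return []
    count = int(lines[0])
    feats = []
    for ln in lines[1 : 1 + count]:
        parts = ln.split()
        k = int(parts[0])
        members = tuple(int(x) for x in parts[1 : 1 + k])
        ftype = _TAG_TO_TYPE[parts[1 + k]]
        feats.append(FeaturePoint.from_members(ftype, atoms, members))
    return feats


def estimate_rotors(mol: Chem.Mol) -> int:
    """Effective rotors approximated as acyclic non-terminal single bonds
    between heavy atoms; 0 when the record carries no bonds."""
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        if a.GetDegree() > 1 and b.GetDegree() > 1:
            n += 1
    return n


def read_sdf(path: str | Path, with_metadata: bool = False):
    """Read conformers from an SDF V2000 file.

    Hydrogens are dropped; features come from the feature tag when present.
    Malformed records (unparseable mol block, bad cid, feature index out of
    range) are skipped with a logged warning.  V3000 records are not
    supported.  With ``with_metadata`` a parallel list of dicts
    (n_components, rotor_count, elements) is returned for eligibility
    checks.
    """
    text = Path(path).read_text()
    if "V3000" in text:
        raise ValueError("SDF V3000 records are not supported")
    conformers: list[Conformer] = []
    metadata: list[dict] = []
    n_skipped = 0
    with open(path, "rb") as fh:
        for i, mol in enumerate(Chem.ForwardSDMolSupplier(fh, sanitize=False, removeHs=False)):
            if mol is None or mol.GetNumConformers() == 0:
                log.warning("skipping unparseable SDF record %d", i)
                n_skipped += 1
                continue
            try:
                cid = int(mol.GetProp("_Name"))
                pos = mol.GetConformer().GetPositions()
                atoms = [
                    Atom(a.GetSymbol(), pos[a.GetIdx()])
                    for a in mol.GetAtoms()
                    if a.GetAtomicNum() != 1
                ]
                feats = (
                    _parse_features(mol.GetProp(FEATURE_TAG), atoms)
                    if mol.HasProp(FEATURE_TAG)
                    else []
                )
                conformers.append(Conformer(cid=cid, atoms=atoms, features=feats))
            except (ValueError, KeyError, IndexError) as exc:
                log.warning("skipping SDF record %d: %s", i, exc)
                n_skipped += 1
                continue
            metadata.append(
                {
                    "n_components": len(Chem.GetMolFrags(mol)) if mol.GetNumBonds() else 1,
                    "rotor_count": estimate_rotors(mol),
                    "elements": sorted({a.GetSymbol() for a in mol.GetAtoms()}),
                }
            )
    if n_skipped:
        log.warning("%d SDF record(s) skipped", n_skipped)
    return (conformers, metadata) if with_metadata else conformers


# ---------------------------------------------------------------------------
# assay CSV


def read_assays(path: str | Path) -> list[AssayTable]:
    """Assay outcome CSV with columns aid, cid, outcome, assay_type.

    Rows are grouped by aid; a blank or unknown assay_type maps to
    "unspecified"; conflicting duplicate (aid, cid) outcomes resolve to
    noninactive with a warning.
    """
    df = pd.read_csv(path, dtype={"outcome": str, "assay_type": str})
    missing = [c for c in ("aid", "cid", "outcome", "assay_type") if c not in df.columns]
    if missing:
        raise ValueError(f"assay CSV missing columns: {', '.join(missing)}")
    tables = []
    for aid, group in df.groupby("aid", sort=True):
        raw = group["assay_type"].iloc[0]
        category = str(raw).strip().lower() if pd.notna(raw) else ""
        if category not in ASSAY_CATEGORIES:
            category = "unspecified"
        rows = [(int(r.cid), str(r.outcome)) for r in group.itertuples()]
        tables.append(AssayTable.from_rows(int(aid), category, rows))
    return tables


def write_assays(assays: Iterable[AssayTable], path: str | Path) -> None:
    rows = [
        {"aid": a.aid, "cid": cid, "outcome": a.outcomes[cid], "assay_type": a.category}
        for a in sorted(assays, key=lambda a: a.aid)
        for cid in sorted(a.outcomes)
    ]
    pd.DataFrame(rows, columns=["aid", "cid", "outcome", "assay_type"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# score TSV


def _transform_cols(prefix: str) -> list[str]:
    return [f"{prefix}_r{i}{j}" for i in range(1, 4) for j in range(1, 4)] + [
        f"{prefix}_t{i}" for i in range(1, 4)
    ]

SCORE_COLUMNS = (
    ["cid_a", "cid_b"] + list(MEASURES) + _transform_cols("stopt") + _transform_cols("ctopt")
)


def write_scores(records: Iterable[SimilarityRecord], path: str | Path) -> None:
    """One row per unordered pair: six scores (4 dp) and both transforms
    (6 dp).  ComboT columns are sums of the rounded ST/CT columns."""
    rows = []
    for r in sorted(records, key=lambda r: (r.cid_a, r.cid_b)):
        st_s, ct_s = round(r.st_stopt, 4), round(r.ct_stopt, 4)
        st_c, ct_c = round(r.st_ctopt, 4), round(r.ct_ctopt, 4)
        row = [r.cid_a, r.cid_b, st_s, ct_s, round(st_s + ct_s, 4), st_c, ct_c, round(st_c + ct_c, 4)]
        for t in (r.transform_stopt, r.transform_ctopt):
            row.extend(round(v, 6) for v in t.rotation.ravel())
            row.extend(round(v, 6) for v in t.translation)
        rows.append(row)
    pd.DataFrame(rows, columns=SCORE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_scores(path: str | Path) -> dict[tuple[int, int], SimilarityRecord]:
    df = pd.read_csv(path, sep="\t")
    out: dict[tuple[int, int], SimilarityRecord] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        transforms = []
        for prefix in ("stopt", "ctopt"):
            rot = np.array([[d[f"{prefix}_r{i}{j}"] for j in range(1, 4)] for i in range(1, 4)])
            trans = np.array([d[f"{prefix}_t{i}"] for i in range(1, 4)])
            # serialized at 6 dp; re-orthonormalize via SVD before validation
            u, _, vt = np.linalg.svd(rot)
            transforms.append(RigidTransform(u @ vt, trans))
        key = (int(d["cid_a"]), int(d["cid_b"]))
        out[key] = SimilarityRecord(
            cid_a=key[0],
            cid_b=key[1],
            st_stopt=float(d["st_stopt"]),
            ct_stopt=float(d["ct_stopt"]),
            combo_stopt=float(d["st_stopt"]) + float(d["ct_stopt"]),
            st_ctopt=float(d["st_ctopt"]),
            ct_ctopt=float(d["ct_ctopt"]),
            combo_ctopt=float(d["st_ctopt"]) + float(d["ct_ctopt"]),
            transform_stopt=transforms[0],
            transform_ctopt=transforms[1],
        )
    return out


# ---------------------------------------------------------------------------
# descriptor / statistics TSVs

DESCRIPTOR_COLUMNS = [
    "cid", "heavy_atoms", "volume", "qx", "qy", "qz",
    "n_donor", "n_acceptor", "n_anion", "n_cation", "n_hydrophobe", "n_ring", "n_total",
]


def write_descriptors(descriptors: Iterable[DescriptorSet], path: str | Path) -> None:
    rows = [
        [
            d.cid, d.heavy_atom_count, round(d.volume, 4),
            round(d.q[0], 4), round(d.q[1], 4), round(d.q[2], 4),
            d.feature_counts["donor"], d.feature_counts["acceptor"],
            d.feature_counts["anion"], d.feature_counts["cation"],
            d.feature_counts["hydrophobe"], d.feature_counts["ring"], d.total_features,
        ]
        for d in sorted(descriptors, key=lambda d: d.cid)
    ]
    pd.DataFrame(rows, columns=DESCRIPTOR_COLUMNS).to_csv(path, sep="\t", index=False)


def per_aid_columns() -> list[str]:
    cols = ["aid", "category", "n_nn", "n_ni"]
    for m in MEASURES:
        cols.extend(f"{m}_{f}" for f in STAT_FIELDS)
    return cols


def write_per_aid(stats: Iterable[PerAidStats], path: str | Path) -> None:
    rows = []
    for s in sorted(stats, key=lambda s: s.aid):
        row: list = [s.aid, s.category, s.n_nn, s.n_ni]
        for m in MEASURES:
            ms = s.measures[m]
            row.extend(round(getattr(ms, f), 6) for f in STAT_FIELDS)
        rows.append(row)
    pd.DataFrame(rows, columns=per_aid_columns()).to_csv(path, sep="\t", index=False)


def read_per_aid(path: str | Path) -> list[PerAidStats]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        measures = {
            m: MeasureStats(*(float(d[f"{m}_{f}"]) for f in STAT_FIELDS)) for m in MEASURES
        }
        out.append(
            PerAidStats(
                aid=int(d["aid"]), category=str(d["category"]),
                n_nn=int(d["n_nn"]), n_ni=int(d["n_ni"]), measures=measures,
            )
        )
    return out


def write_aggregate(agg: pd.DataFrame, path: str | Path) -> None:
    agg.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_histogram(hist: Histogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "bin_center": np.round(hist.bin_centers, 4),
            "count": hist.counts,
            "cumulative_pct": np.round(hist.cumulative_pct, 4),
        }
    )
    df.to_csv(path, index=False)
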