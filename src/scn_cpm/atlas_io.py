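"""Readers and writers for atlases, regional GMV tables, metadata, and reports.

All tabular formats are TSV with a header row (UTF-8, ``.`` decimal
separator); CSV is accepted through the ``sep`` argument. Gray-matter maps
and parcellation label volumes are NIfTI-1 images read with :mod:`nibabel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from scn_cpm.cpm_engine import CPMResult, SignedEdgeMasks
from scn_cpm.scn_builder import EdgeIndex

#: absolute tolerance for comparing NIfTI affines; resampling is out of
#: scope, so grids must agree to near machine identity.
AFFINE_ATOL = 1e-4

UNASSIGNED = "UNASSIGNED"


@dataclass
class RegionAtlas:
    """An ordered brain parcellation with optional canonical-network labels.

    Parameters
    ----------
    region_ids:
        Unique integer labels, in the order regions appear in GMV tables.
    region_names:
        Unique text names, aligned with ``region_ids``.
    canonical_network:
        Optional map ``region_id -> network name`` assigning regions to
        large-scale canonical systems (e.g. medial frontal, frontoparietal,
        default mode, subcortical-cerebellum, motor, visual).
    label_volume:
        Optional 3-D integer NIfTI image in which voxel value equals the
        region_id (0 = background), used for regional extraction.
    """

    region_ids: list[int]
    region_names: list[str]
    canonical_network: dict[int, str] | None = None
    label_volume: object | None = None  # nibabel spatial image

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.region_names):
            raise ValueError("region_ids and region_names must have equal length")
        if len(self.region_ids) < 2:
            raise ValueError("an atlas needs at least 2 regions")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("region_ids must be unique")
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region_names must be unique")
        if self.canonical_network is not None:
            unknown = set(self.canonical_network) - set(self.region_ids)
            if unknown:
                raise ValueError(
                    f"canonical_network refers to unknown region_ids: {sorted(unknown)}"
                )

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def network_of(self, region_id: int) -> str:
        """Canonical network of a region, ``UNASSIGNED`` when unmapped."""
        if self.canonical_network is None:
            return UNASSIGNED
        return self.canonical_network.get(region_id, UNASSIGNED)


@dataclass
class CohortGMV:
    """Per-subject regional gray-matter volumes with score and covariates.

    ``gmv`` is a subjects x regions matrix of mean regional GMV (any
    consistent volume unit). ``score`` is the behavioral severity score
    (FTND, 0-10). ``covariates`` holds named nuisance vectors such as total
    intracranial volume (TIV, mm^3), image quality rating (IQR,
    dimensionless) and age (years).
    """

    subject_ids: list[str]
    gmv: np.ndarray
    score: np.ndarray
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gmv = np.asarray(self.gmv, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_id")
        if self.gmv.ndim != 2 or self.gmv.shape[0] != n:
            raise ValueError("gmv must be a subjects x regions matrix")
        if n < 4:
            raise ValueError("at least 4 subjects are required")
        if self.score.shape != (n,):
            raise ValueError("score length must equal the subject count")
        if np.isnan(self.gmv).any():
            i, j = np.argwhere(np.isnan(self.gmv))[0]
            raise ValueError(f"missing GMV value for subject {self.subject_ids[i]}, region column {j}")
        for name, vec in self.covariates.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise ValueError(f"covariate {name!r} length must equal the subject count")
            self.covariates[name] = vec

    @property
    def n_subjects(self) -> int:
        return self.gmv.shape[0]

    @property
    def n_regions(self) -> int:
        return self.gmv.shape[1]


def load_region_table(path: str | Path) -> RegionAtlas:
    """Read an atlas region table (columns ``region_id``, ``region_name``)."""
    df = pd.read_csv(path, sep="\t")
    if not {"region_id", "region_name"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns region_id and region_name")
    return RegionAtlas(
        region_ids=[int(x) for x in df["region_id"]],
        region_names=[str(x) for x in df["region_name"]],
    )


def bundled_aal116(with_canonical: bool = True) -> RegionAtlas:
    """The packaged 116-region anatomical parcellation fixture.

    Region ids run 1..116 in the conventional AAL order (cerebral regions,
    cerebellar hemispheres, vermis). The bundled canonical-network mapping
    is a best-effort editable default; substitute your own via
    :func:`load_canonical_mapping` when the assignment matters.
    """
    data = resources.files("scn_cpm.data")
    atlas = load_region_table(data / "aal116_regions.tsv")
    if with_canonical:
        atlas = load_canonical_mapping(data / "aal116_canonical.tsv", atlas)
    return atlas


def load_canonical_mapping(path, atlas: RegionAtlas) -> RegionAtlas:
    """Attach a region_id -> canonical-network mapping read from a TSV.

    Regions absent from the table are assigned the sentinel network
    ``UNASSIGNED`` (implicitly, via :meth:`RegionAtlas.network_of`).
    """
    df = pd.read_csv(path, sep="\t")
    if not {"region_id", "network"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns region_id and network")
    known = set(atlas.region_ids)
    mapping: dict[int, str] = {}
    for rid, net in zip(df["region_id"], df["network"]):
        rid = int(rid)
        if rid not in known:
            raise ValueError(f"{path}: region_id {rid} is not in the atlas")
        mapping[rid] = str(net)
    return replace(atlas, canonical_network=mapping)


def load_gmv_table(
    path: str | Path,
    metadata_path: str | Path,
    sep: str = "\t",
    score_column: str = "score",
) -> CohortGMV:
    """Load a subjects x regions GMV table plus per-subject metadata.

    The GMV table has a ``subject_id`` column followed by one column per
    region; the metadata table has ``subject_id``, the score column, and any
    number of covariate columns. Rows are aligned by subject_id and returned
    in metadata order.
    """
    gmv_df = pd.read_csv(path, sep=sep)
    meta_df = pd.read_csv(metadata_path, sep=sep)
    for name, df in ((path, gmv_df), (metadata_path, meta_df)):
        if "subject_id" not in df.columns:
            raise ValueError(f"{name}: missing subject_id column")
        if df["subject_id"].duplicated().any():
            dups = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].astype(str))
            raise ValueError(f"{name}: duplicate subject_id {dups}")
    if score_column not in meta_df.columns:
        raise ValueError(f"{metadata_path}: missing score column {score_column!r}")

    gmv_ids = set(gmv_df["subject_id"].astype(str))
    meta_ids = set(meta_df["subject_id"].astype(str))
    if gmv_ids != meta_ids:
        only_gmv = sorted(gmv_ids - meta_ids)
        only_meta = sorted(meta_ids - gmv_ids)
        raise ValueError(
            "subject_id mismatch between tables: "
            f"only in GMV table {only_gmv}; only in metadata {only_meta}"
        )

    gmv_df = gmv_df.set_index(gmv_df["subject_id"].astype(str)).drop(columns="subject_id")
    order = meta_df["subject_id"].astype(str).tolist()
    gmv_df = gmv_df.loc[order]

    if gmv_df.isna().any().any():
        col = gmv_df.columns[gmv_df.isna().any()][0]
        subj = gmv_df.index[gmv_df[col].isna()][0]
        raise ValueError(f"missing GMV value for subject {subj}, region {col}")

    covariates = {
        c: meta_df[c].to_numpy(dtype=float)
        for c in meta_df.columns
        if c not in ("subject_id", score_column)
    }
    return CohortGMV(
        subject_ids=order,
        gmv=gmv_df.to_numpy(dtype=float),
        score=meta_df[score_column].to_numpy(dtype=float),
        covariates=covariates,
    )


def extract_regional_gmv(gm_maps: Sequence[object], atlas: RegionAtlas) -> np.ndarray:
    """Mean GMV per atlas region for each subject's gray-matter map.

    Entry (i, j) is the arithmetic mean of map i over voxels whose label in
    ``atlas.label_volume`` equals ``atlas.region_ids[j]``; background voxels
    (label 0) never contribute. All maps must share the label volume's grid
    (identical shape, affines equal within ``AFFINE_ATOL``).
    """
    if atlas.label_volume is None:
        raise ValueError("atlas has no label_volume for regional extraction")
    label_img = atlas.label_volume
    labels = np.asarray(label_img.get_fdata(), dtype=np.int64)
    ids = np.asarray(atlas.region_ids, dtype=np.int64)

    counts = np.array([(labels == rid).sum() for rid in ids])
    if (counts == 0).any():
        missing = [atlas.region_names[k] for k in np.nonzero(counts == 0)[0]]
        raise ValueError(f"regions with zero voxels in label volume: {missing}")

    out = np.empty((len(gm_maps), len(ids)), dtype=float)
    for i, img in enumerate(gm_maps):
        if img.shape != label_img.shape:
            raise ValueError(
                f"map {i}: shape {img.shape} does not match label volume {label_img.shape}"
            )
        if not np.allclose(img.affine, label_img.affine, atol=AFFINE_ATOL, rtol=0.0):
            raise ValueError(f"map {i}: affine does not match label volume (atol={AFFINE_ATOL})")
        data = np.asarray(img.get_fdata(), dtype=float)
        out[i] = ndimage.mean(data, labels=labels, index=ids)
    return out


# ---------------------------------------------------------------------------
# result reports


def _fmt(x: float) -> str:
    return repr(float(x))


def write_report(
    result: CPMResult,
    atlas: RegionAtlas,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a deterministic set of report files for a CPM run.

    Produces ``edges.tsv`` (per selected edge: regions, sign, fraction of
    folds selecting it), ``degrees.tsv`` (consensus node degrees),
    ``canonical_counts_{positive,negative}.tsv`` (within/between canonical
    network edge counts for the consensus masks) and ``summary.json``.
    Rewriting the same result yields byte-identical files.
    """
    from scn_cpm import __version__
    from scn_cpm import network_anatomy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_index = result.edge_index
    if atlas.n_regions != edge_index.n_regions:
        raise ValueError("atlas region count does not match the result's edge index")
    pairs = edge_index.pairs
    names = atlas.region_names
    ids = atlas.region_ids

    n_folds = result.fold_positive.shape[0]
    paths: dict[str, Path] = {}

    edge_path = out_dir / "edges.tsv"
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("region_i_id\tregion_j_id\tregion_i\tregion_j\tsign\tfold_frequency\n")
        for sign, folds in (("+", result.fold_positive), ("-", result.fold_negative)):
            freq = folds.sum(axis=0) / n_folds
            for e in np.nonzero(freq > 0)[0]:
                a, b = pairs[e]
                fh.write(
                    f"{ids[a]}\t{ids[b]}\t{names[a]}\t{names[b]}\t{sign}\t{_fmt(freq[e])}\n"
                )
    paths["edges"] = edge_path

    deg_pos = network_anatomy.node_degree(result.consensus, edge_index, atlas, "positive")
    deg_neg = network_anatomy.node_degree(result.consensus, edge_index, atlas, "negative")
    deg = pd.DataFrame(
        {
            "region_id": ids,
            "region_name": names,
            "degree_positive": deg_pos["degree"].to_numpy(),
            "degree_negative": deg_neg["degree"].to_numpy(),
        }
    )
    deg_path = out_dir / "degrees.tsv"
    deg.to_csv(deg_path, sep="\t", index=False)
    paths["degrees"] = deg_path

    for sign in ("positive", "negative"):
        mat = network_anatomy.canonical_summary(result.consensus, edge_index, atlas, sign)
        p = out_dir / f"canonical_counts_{sign}.tsv"
        mat.to_csv(p, sep="\t", index_label="network")
        paths[f"canonical_{sign}"] = p

    summary = {
        "performance_r": None if np.isnan(result.performance_r) else result.performance_r,
        "permutation_p": result.p_perm,
        "n_permutations": int(result.null_r.size),
        "threshold_p": result.threshold_p,
        "mode": result.mode,
        "seed": result.seed,
        "n_subjects": int(result.predicted.size),
        "n_regions": edge_index.n_regions,
        "n_edges": edge_index.n_edges,
        "n_consensus_positive": int(result.consensus.positive.sum()),
        "n_consensus_negative": int(result.consensus.negative.sum()),
        "version": __version__,
    }
    sum_path = out_dir / "summary.json"
    sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    paths["summary"] = sum_path
    return paths


def read_edge_report(path: str | Path, edge_index: EdgeIndex, atlas: RegionAtlas) -> SignedEdgeMasks:
    """Reconstruct consensus masks from an ``edges.tsv`` report file.

    Consensus edges are those written with fold-selection frequency 1.
    """
    df = pd.read_csv(path, sep="\t")
    E = edge_index.n_edges
    pos = np.zeros(E, dtype=bool)
    neg = np.zeros(E, dtype=bool)
    id_to_index = {rid: k for k, rid in enumerate(atlas.region_ids)}
    for _, row in df.iterrows():
        if float(row["fold_frequency"]) < 1.0:
            continue
        a = id_to_index[int(row["region_i_id"])]
        b = id_to_index[int(row["region_j_id"])]
        e = edge_index.index_of(a, b)
        if row["sign"] == "+":
            pos[e] = True
        else:
            neg[e] = True
    return SignedEdgeMasks(positive=pos, negative=neg, threshold_p=np.nan)
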