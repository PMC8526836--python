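"""Plain-text and NIfTI serialization for the pipeline's containers.

Connectomes, FC matrices and BOLD runs travel as TSV (square matrix with a
header row of labels, or region x time with a label column); expression
atlases as long-format TSV (donor, gene, location, value); gene lists as
one identifier per line; fit results and cluster solutions as JSON; voxel
datasets as 4-D NIfTI plus a coordinate sidecar handled through nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, VoxelDataset
from .dmf import FICSolution, StructuralConnectome
from .enrichment import GeneExpressionAtlas, GeneSet
from .hemodynamics import BOLDTimeseries

__all__ = ["write_connectome_tsv", "read_connectome_tsv",
           "write_fc_tsv", "read_fc_tsv",
           "write_bold_tsv", "read_bold_tsv",
           "write_gene_list", "read_gene_list",
           "write_atlas_tsv", "read_atlas_tsv",
           "write_fic_json", "read_fic_json",
           "write_voxels_nifti", "read_voxels_nifti"]


def _write_square(path, labels, M) -> None:
    pd.DataFrame(M, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="region")


def _read_square(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def write_connectome_tsv(path, connectome: StructuralConnectome) -> None:
    _write_square(path, connectome.labels, connectome.C)


def read_connectome_tsv(path) -> StructuralConnectome:
    labels, C = _read_square(path)
    return StructuralConnectome(labels=labels, C=C)


def write_fc_tsv(path, fc: FCMatrix) -> None:
    _write_square(path, fc.labels, fc.R)


def read_fc_tsv(path) -> FCMatrix:
    from .connectivity import fisher_z
    labels, R = _read_square(path)
    return FCMatrix(labels=labels, R=R, Z=fisher_z(R))


def write_bold_tsv(path, bold: BOLDTimeseries) -> None:
    labels = bold.labels or [f"r{i}" for i in range(bold.n_regions)]
    df = pd.DataFrame(bold.Y, index=labels, columns=bold.t)
    df.to_csv(path, sep="\t", index_label="region")


def read_bold_tsv(path, tr_s: float | None = None) -> BOLDTimeseries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    t = df.columns.to_numpy(dtype=float)
    if tr_s is None:
        tr_s = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return BOLDTimeseries(t=t, Y=df.to_numpy(dtype=float), tr_s=tr_s,
                          labels=[str(i) for i in df.index])


def write_gene_list(path, genes) -> None:
    members = sorted(genes.members if isinstance(genes, GeneSet) else genes)
    Path(path).write_text("\n".join(members) + "\n")


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()]


def write_atlas_tsv(path, atlas: GeneExpressionAtlas) -> None:
    d, g, l = np.meshgrid(range(len(atlas.donors)), range(len(atlas.genes)),
                          range(len(atlas.locations)), indexing="ij")
    df = pd.DataFrame({
        "donor": np.asarray(atlas.donors)[d.ravel()],
        "gene": np.asarray(atlas.genes)[g.ravel()],
        "location": np.asarray(atlas.locations)[l.ravel()],
        "value": atlas.X.ravel()})
    df.to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path) -> GeneExpressionAtlas:
    df = pd.read_csv(path, sep="\t")
    donors = sorted(df["donor"].unique())
    genes = sorted(df["gene"].unique())
    locations = sorted(df["location"].unique())
    X = (df.pivot_table(index=["donor", "gene"], columns="location",
                        values="value", sort=True)
           .reindex(pd.MultiIndex.from_product([donors, genes]))
           .reindex(columns=locations)
           .to_numpy()
           .reshape(len(donors), len(genes), len(locations)))
    return GeneExpressionAtlas(donors=donors, genes=genes,
                               locations=locations, X=X)


def write_fic_json(path, labels, fic: FICSolution) -> None:
    payload = {"labels": list(labels), "J": fic.J.tolist(),
               "achieved_rates": fic.achieved_rates.tolist(),
               "converged": bool(fic.converged)}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fic_json(path) -> tuple[list[str], FICSolution]:
    payload = json.loads(Path(path).read_text())
    return payload["labels"], FICSolution(
        J=np.asarray(payload["J"], dtype=float),
        converged=bool(payload["converged"]),
        achieved_rates=np.asarray(payload["achieved_rates"], dtype=float))


def write_voxels_nifti(path, ds: VoxelDataset, voxel_size_mm: float = 1.0) -> None:
    """4-D NIfTI with voxels unrolled along the first axis."""
    import nibabel as nib
    img_data = ds.data[:, None, None, :]
    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    img = nib.Nifti1Image(img_data, affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + (ds.tr_s,))
    nib.save(img, str(path))
    np.savetxt(str(path) + ".coords.tsv", ds.coords, delimiter="\t")


def read_voxels_nifti(path) -> VoxelDataset:
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = data.reshape(-1, data.shape[-1])
    coords = np.loadtxt(str(path) + ".coords.tsv", delimiter="\t", ndmin=2)
    tr = float(img.header.get_zooms()[-1]) or 1.0
    return VoxelDataset(data=data, coords=coords, tr_s=tr)
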