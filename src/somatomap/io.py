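"""Text/NIfTI I/O for the package's containers.

Time-series go to NIfTI-1 (a dummy 1 x 1 x V grid over volumes) or
tab-delimited text; meshes to OFF; Fourier maps and trial tables to CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import BehavioralTrialTable, CortexPatch, FourierMap, TimeSeriesMatrix


def write_timeseries_nifti(ts: TimeSeriesMatrix, path):
    import nibabel as nib
    vol = ts.data.T.reshape(1, 1, ts.n_vertices, ts.n_volumes)
    img = nib.Nifti1Image(np.asarray(vol, np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_s))
    nib.save(img, str(path))


def read_timeseries_nifti(path) -> TimeSeriesMatrix:
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return TimeSeriesMatrix(data=data.reshape(-1, data.shape[-1]).T, tr_s=tr)


def write_timeseries_text(ts: TimeSeriesMatrix, path):
    """Tab-delimited volumes x vertices matrix; TR on a comment line."""
    with open(path, "w") as fh:
        fh.write(f"# tr_s={ts.tr_s}\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.8g")


def read_timeseries_text(path) -> TimeSeriesMatrix:
    tr = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "tr_s=" in first:
            tr = float(first.split("tr_s=")[1])
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        else:
            fh.seek(0)
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return TimeSeriesMatrix(data=data, tr_s=tr)


def write_mesh_off(patch: CortexPatch, path):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{patch.n_vertices} {len(patch.faces)} 0\n")
        for v in patch.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in patch.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh_off(path):
    """Read an OFF mesh; returns (vertices, faces)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    head = 4
    verts = np.array(tokens[head:head + 3 * nv], float).reshape(nv, 3)
    faces = []
    i = head + 3 * nv
    for _ in range(nf):
        k = int(tokens[i])
        faces.append([int(t) for t in tokens[i + 1:i + 1 + k]])
        i += k + 1
    return verts, np.array(faces, int)


def write_fourier_map(fmap: FourierMap, path):
    fmap.to_frame().to_csv(path, index=False)


def write_trials_csv(trials: BehavioralTrialTable, path):
    trials.trials.to_csv(
        path, index=False,
        columns=["stimulated_digit", "reported_digit", "trial"])


def read_trials_csv(path, n_trials_per_digit: int | None = None) -> BehavioralTrialTable:
    df = pd.read_csv(path)
    if n_trials_per_digit is None:
        n_trials_per_digit = int(df.groupby("stimulated_digit").size().max())
    return BehavioralTrialTable(trials=df, n_trials_per_digit=n_trials_per_digit)
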