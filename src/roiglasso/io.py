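"""HDF5 containers for simulated datasets and filtered problems.

Layout of a simulation container::

    /meta                       (attrs: n_subjects, T, snr, roi order, ...)
    /subjects/<k>/forward/<i>   N x p_i lead-field block
    /subjects/<k>/coords/<i>    p_i x 3 vertex coordinates
    /subjects/<k>/adj/<i>       adjacency in CSR (indices, indptr)
    /subjects/<k>/truth/<i>     p_i x T ground-truth activity
    /subjects/<k>/active/<i>    active vertex indices
    /subjects/<k>/Y, signal, noise

and of a filtered-problem container::

    /X, /Ytilde, /Ystack, /gammas, /groups/<i>
    /bases/Vd, /bases/singular_values
    /bases/<k>/<i>/{P, means}
"""

from __future__ import annotations

import h5py
import numpy as np
from scipy.sparse import csr_matrix

from .forward_sim import (RoiGeometry, SensorRecordings, SimulationTruth,
                          SubjectForward)
from .reduction import FilteredProblem, SpatialBasisBlock, TemporalBasis

__all__ = ["save_simulation", "load_simulation", "save_filtered",
           "load_filtered"]


def save_simulation(path, forwards, truths, recordings,
                    meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        m = f.create_group("meta")
        m.attrs["n_subjects"] = len(forwards)
        m.attrs["roi_names"] = [r.name for r in forwards[0].rois]
        m.attrs["T"] = truths[0].T
        for key, val in (meta or {}).items():
            m.attrs[key] = val
        for k, (fwd, truth, rec) in enumerate(
                zip(forwards, truths, recordings)):
            g = f.create_group(f"subjects/{k}")
            g.attrs["n_sensors"] = fwd.n_sensors
            if truth.snr is not None:
                g.attrs["snr"] = truth.snr
            if truth.noise_sigma is not None:
                g.attrs["noise_sigma"] = truth.noise_sigma
            for i, roi in enumerate(fwd.rois):
                g.create_dataset(f"forward/{i}", data=fwd.F_blocks[i])
                g.create_dataset(f"coords/{i}", data=roi.vertex_coords)
                g.create_dataset(f"adj/{i}/indices",
                                 data=roi.adjacency.indices)
                g.create_dataset(f"adj/{i}/indptr",
                                 data=roi.adjacency.indptr)
                g.create_dataset(f"truth/{i}", data=truth.beta_blocks[i])
                g.create_dataset(f"active/{i}", data=truth.active[i])
            g.create_dataset("Y", data=rec.Y)
            g.create_dataset("signal", data=rec.signal)
            g.create_dataset("noise", data=rec.noise)


def load_simulation(path):
    """Inverse of :func:`save_simulation`."""
    forwards, truths, recordings = [], [], []
    with h5py.File(path, "r") as f:
        names = [s if isinstance(s, str) else s.decode()
                 for s in f["meta"].attrs["roi_names"]]
        T = int(f["meta"].attrs["T"])
        n_subjects = int(f["meta"].attrs["n_subjects"])
        for k in range(n_subjects):
            g = f[f"subjects/{k}"]
            rois, F_blocks, beta_blocks, active = [], [], [], []
            for i, name in enumerate(names):
                coords = g[f"coords/{i}"][()]
                p = coords.shape[0]
                indices = g[f"adj/{i}/indices"][()]
                indptr = g[f"adj/{i}/indptr"][()]
                adj = csr_matrix((np.ones(indices.size), indices, indptr),
                                 shape=(p, p))
                rois.append(RoiGeometry(roi_id=i + 1, name=name,
                                        vertex_coords=coords,
                                        adjacency=adj))
                F_blocks.append(g[f"forward/{i}"][()])
                beta_blocks.append(g[f"truth/{i}"][()])
                active.append(g[f"active/{i}"][()].astype(int))
            fwd = SubjectForward(subject_id=k, rois=rois,
                                 F_blocks=F_blocks,
                                 n_sensors=int(g.attrs["n_sensors"]))
            truth = SimulationTruth(
                beta_blocks=beta_blocks, active=active, amplitudes={},
                T=T, snr=float(g.attrs.get("snr", np.nan)),
                noise_sigma=float(g.attrs.get("noise_sigma", np.nan)))
            rec = SensorRecordings(subject_id=k, Y=g["Y"][()],
                                   signal=g["signal"][()],
                                   noise=g["noise"][()])
            forwards.append(fwd)
            truths.append(truth)
            recordings.append(rec)
    return forwards, truths, recordings


def save_filtered(path, problem: FilteredProblem) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=problem.X)
        f.create_dataset("Ytilde", data=problem.Y_tilde)
        f.create_dataset("Ystack", data=problem.Y_stack)
        f.create_dataset("gammas", data=problem.gammas)
        f.attrs["n_sensors"] = problem.n_sensors
        f.attrs["n_subjects"] = problem.n_subjects
        f.attrs["T"] = problem.T
        f.attrs["resid_var_remainder"] = problem.resid_var_remainder
        f.attrs["total_center_ss"] = problem.total_center_ss
        f.attrs["var_threshold"] = problem.temporal.var_threshold
        for i, cols in enumerate(problem.group_cols):
            f.create_dataset(f"groups/{i}/cols", data=cols)
            for k, sc in enumerate(problem.subject_cols[i]):
                f.create_dataset(f"groups/{i}/subject/{k}", data=sc)
        f.create_dataset("bases/Vd", data=problem.temporal.V_d)
        f.create_dataset("bases/singular_values",
                         data=problem.temporal.singular_values)
        for k, subj in enumerate(problem.spatial):
            for i, blk in enumerate(subj):
                f.create_dataset(f"bases/{k}/{i}/P", data=blk.P)
                f.create_dataset(f"bases/{k}/{i}/means",
                                 data=blk.column_means)
                f[f"bases/{k}/{i}"].attrs["n_informative"] = \
                    blk.n_informative


def load_filtered(path) -> FilteredProblem:
    with h5py.File(path, "r") as f:
        S = int(f.attrs["n_subjects"])
        R = len(f["groups"])
        group_cols = [f[f"groups/{i}/cols"][()].astype(int)
                      for i in range(R)]
        subject_cols = [[f[f"groups/{i}/subject/{k}"][()].astype(int)
                         for k in range(S)] for i in range(R)]
        spatial = []
        for k in range(S):
            subj = []
            for i in range(R):
                g = f[f"bases/{k}/{i}"]
                subj.append(SpatialBasisBlock(
                    P=g["P"][()], column_means=g["means"][()],
                    n_informative=int(g.attrs["n_informative"])))
            spatial.append(subj)
        tb = TemporalBasis(
            V_d=f["bases/Vd"][()],
            singular_values=f["bases/singular_values"][()],
            var_threshold=float(f.attrs["var_threshold"]))
        return FilteredProblem(
            X=f["X"][()], Y_tilde=f["Ytilde"][()],
            group_cols=group_cols, subject_cols=subject_cols,
            gammas=f["gammas"][()], spatial=spatial, temporal=tb,
            n_sensors=int(f.attrs["n_sensors"]), n_subjects=S,
            T=int(f.attrs["T"]), Y_stack=f["Ystack"][()],
            resid_var_remainder=float(f.attrs["resid_var_remainder"]),
            total_center_ss=float(f.attrs["total_center_ss"]))
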