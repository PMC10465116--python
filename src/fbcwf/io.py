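"""File I/O for stacks, CTF tables, coefficient and covariance containers.

Stacks travel as MRC/MRCS; CTF parameters and group maps as CSV; the
coefficient and covariance containers are NumPy ``.npz`` archives that
embed the basis index table (n, k, lambda, normalizer) so they are
self-describing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import BasisSpec, CoefficientSet
from .covariance import BlockCovariance, MeanCoefficients
from .ctf import CTFParams
from .mrc import read_mrc, write_mrc
from .stack import ImageStack

CTF_COLUMNS = ["group_id", "defocus_A", "voltage_kV", "cs_mm",
               "amplitude_contrast", "pixel_size_A"]


def read_stack(path, group_map: np.ndarray | None = None) -> ImageStack:
    data, pixel = read_mrc(path)
    return ImageStack(data=data.astype(float), pixel_size_A=pixel,
                      group_ids=group_map)


def write_stack(stack: ImageStack, path) -> None:
    write_mrc(path, stack.data, pixel_size_A=stack.pixel_size_A)


def read_ctf_table(path) -> list[CTFParams]:
    df = pd.read_csv(path)
    missing = [c for c in CTF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CTF table {path} lacks columns {missing}")
    return [CTFParams(defocus_A=r.defocus_A, voltage_kV=r.voltage_kV,
                      cs_mm=r.cs_mm, amplitude_contrast=r.amplitude_contrast,
                      pixel_size_A=r.pixel_size_A, group_id=int(r.group_id))
            for r in df.itertuples(index=False)]


def write_ctf_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_group_map(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "group_id" not in df.columns:
        raise ValueError(f"group map {path} lacks a group_id column")
    return df["group_id"].to_numpy(dtype=np.int64)


def write_group_map(groups: np.ndarray, path) -> None:
    pd.DataFrame({"image_index": np.arange(len(groups)),
                  "group_id": groups}).to_csv(path, index=False)


def read_star_defocus(path) -> pd.DataFrame:
    """Minimal STAR import: extract per-row CTF parameters.

    Parses the first ``loop_`` block and maps the relion defocus columns
    onto the package's CTF table layout (defocus U/V averaged — the radial
    model has no astigmatism).  This is deliberately not a general STAR
    reader; only the defocus-related columns are understood.
    """
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "loop_":
                in_loop = True
                tags, rows = [], []
                continue
            if in_loop and line.startswith("_"):
                tags.append(line.split()[0].lstrip("_"))
                continue
            if in_loop:
                if line.startswith(("data_", "loop_")):
                    break
                parts = line.split()
                if len(parts) == len(tags):
                    rows.append(parts)
    if not tags or not rows:
        raise ValueError(f"{path}: no STAR loop with data rows found")
    df = pd.DataFrame(rows, columns=tags)

    def col(name, default=None):
        if name in df.columns:
            return df[name].astype(float)
        if default is None:
            raise ValueError(f"{path}: missing required STAR column _{name}")
        return pd.Series(default, index=df.index, dtype=float)

    du = col("rlnDefocusU")
    dv = col("rlnDefocusV", None) if "rlnDefocusV" in df.columns else du
    out = pd.DataFrame({
        "group_id": np.arange(len(df)),
        "defocus_A": 0.5 * (du + dv.astype(float)),
        "voltage_kV": col("rlnVoltage", 300.0),
        "cs_mm": col("rlnSphericalAberration", 2.0),
        "amplitude_contrast": col("rlnAmplitudeContrast", 0.07),
        "pixel_size_A": col("rlnImagePixelSize",
                            col("rlnDetectorPixelSize", 1.0).iloc[0]
                            if "rlnDetectorPixelSize" in df.columns else 1.0),
    })
    return out


def _spec_arrays(spec: BasisSpec) -> dict:
    return {"basis_L": spec.L, "basis_bandlimit": spec.bandlimit,
            "basis_n": spec.ns, "basis_k": spec.ks,
            "basis_lambda": spec.roots, "basis_normalizer": spec.normalizers}


def _spec_from_arrays(z) -> BasisSpec:
    return BasisSpec(L=int(z["basis_L"]), bandlimit=float(z["basis_bandlimit"]),
                     ns=z["basis_n"], ks=z["basis_k"],
                     roots=z["basis_lambda"], normalizers=z["basis_normalizer"])


def save_coefficients(path, coeffs: CoefficientSet,
                      weights: np.ndarray | None = None,
                      groups: np.ndarray | None = None,
                      sigma2: float = 1.0) -> None:
    """Coefficient container: coefficients + basis index table, and
    optionally the matching (whitened) CTF weight matrix and group map."""
    payload = {"coefficients": coeffs.data,
               "is_real_image": np.array(coeffs.is_real_image),
               "sigma2": np.array(sigma2), **_spec_arrays(coeffs.spec)}
    if weights is not None:
        payload["ctf_weights"] = np.asarray(weights)
    if groups is not None:
        payload["groups"] = np.asarray(groups, dtype=np.int64)
    np.savez_compressed(path, **payload)


def load_coefficients(path):
    """Returns (CoefficientSet, weights or None, groups or None, sigma2)."""
    with np.load(path) as z:
        spec = _spec_from_arrays(z)
        cs = CoefficientSet(data=z["coefficients"], spec=spec,
                            is_real_image=bool(z["is_real_image"]))
        weights = z["ctf_weights"] if "ctf_weights" in z else None
        groups = z["groups"] if "groups" in z else None
        sigma2 = float(z["sigma2"])
    return cs, weights, groups, sigma2


def save_mean(path, mean: MeanCoefficients) -> None:
    np.savez_compressed(path, mean=mean.vec, **_spec_arrays(mean.spec))


def load_mean(path) -> MeanCoefficients:
    with np.load(path) as z:
        return MeanCoefficients(vec=z["mean"], spec=_spec_from_arrays(z))


def save_covariance(path, cov: BlockCovariance) -> None:
    payload = {f"block_{n}": S for n, S in cov.blocks.items()}
    payload.update(_spec_arrays(cov.spec))
    payload["sigma2"] = np.array(cov.sigma2)
    payload["n_images"] = np.array(cov.n_images)
    np.savez_compressed(path, **payload)


def load_covariance(path) -> BlockCovariance:
    with np.load(path) as z:
        spec = _spec_from_arrays(z)
        blocks = {int(key.split("_", 1)[1]): z[key]
                  for key in z.files if key.startswith("block_")}
        return BlockCovariance(blocks=blocks, spec=spec,
                               sigma2=float(z["sigma2"]),
                               n_images=int(z["n_images"]))
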