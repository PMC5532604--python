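"""Reading and writing the package's file formats.

All formats are plain text: focal and covariate tables are CSV, ethograms
are YAML (or JSON) lists of ``{name, kind}`` records, pedigrees are
``id,sire,dam`` CSV with empty fields for unknown parents, and posterior
samples are stored in a compressed .npz container with a JSON sidecar for
the metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import BinnedDataset, BinningScheme, Ethogram, FocalTable
from .pedigree import Pedigree
from .sampler import PosteriorSamples

__all__ = [
    "read_ethogram",
    "write_ethogram",
    "read_focal_csv",
    "write_focal_csv",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_covariates_csv",
    "save_samples",
    "load_samples",
    "write_binned",
]


def read_ethogram(path) -> Ethogram:
    text = Path(path).read_text()
    records = yaml.safe_load(text)
    return Ethogram.from_records(records)


def write_ethogram(ethogram: Ethogram, path) -> None:
    Path(path).write_text(yaml.safe_dump(ethogram.to_records(), sort_keys=False))


def read_focal_csv(path, ethogram: Ethogram, duration: float = 600.0) -> FocalTable:
    df = pd.read_csv(path)
    return FocalTable.from_dataframe(df, ethogram, duration=duration)


def write_focal_csv(table: FocalTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace("", np.nan)
    return Pedigree.from_dataframe(df)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_dataframe().to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "animal_id" not in df.columns:
        raise ValueError("covariate CSV must have an animal_id column")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def write_binned(data: BinnedDataset, scheme: BinningScheme, out_dir) -> None:
    """Binned levels as CSV plus the cutpoint scheme as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.to_dataframe().to_csv(out / "binned.csv", index=False)
    (out / "binning_scheme.json").write_text(scheme.to_json())


def save_samples(samples: PosteriorSamples, path) -> None:
    path = Path(path)
    arrays = {
        "theta": samples.theta,
        "alpha": samples.alpha,
        "beta": samples.beta,
        "eps": samples.eps,
        "sigma2": samples.sigma2,
        "tau": samples.tau,
        "z": samples.z,
        "chain": samples.chain,
        "iteration": samples.iteration,
        "n_levels": samples.n_levels,
    }
    if samples.u is not None:
        arrays["u"] = samples.u
        arrays["gamma"] = samples.gamma
    np.savez_compressed(path, **arrays)
    meta = {
        "animal_ids": samples.animal_ids,
        "covariate_names": samples.covariate_names,
        "has_genetics": samples.u is not None,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def load_samples(path) -> PosteriorSamples:
    path = Path(path)
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return PosteriorSamples(
        theta=arrays["theta"],
        alpha=arrays["alpha"],
        beta=arrays["beta"],
        u=arrays.get("u"),
        eps=arrays["eps"],
        sigma2=arrays["sigma2"],
        tau=arrays["tau"],
        gamma=arrays.get("gamma"),
        z=arrays["z"],
        chain=arrays["chain"],
        iteration=arrays["iteration"],
        n_levels=arrays["n_levels"],
        animal_ids=list(meta["animal_ids"]),
        covariate_names=list(meta["covariate_names"]),
    )
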