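"""Readers and writers for connectomes, receptor maps, metadata, configs.

Connectomes are square numeric matrices in comma- or whitespace-delimited
text with an optional header row of region labels; receptor maps are either
a two-column TSV (region label, density) or a single numeric column in
matrix order; region metadata is a TSV with one row per region. Run
configurations are flat JSON objects overriding model-parameter defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import Connectome, InvalidParameterError, ModelParameters, ReceptorMap

__all__ = [
    "read_connectome",
    "write_connectome",
    "read_receptor_map",
    "write_receptor_map",
    "read_metadata",
    "write_metadata",
    "read_params",
    "write_params",
]


def _sniff_delimiter(first_line: str) -> str | None:
    return "," if "," in first_line else None  # None = any whitespace


def read_connectome(path: str | Path) -> Connectome:
    """Load a symmetric weight matrix, with an optional label header row."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    tokens = first.strip().split(delim)
    has_header = any(not _is_number(t) for t in tokens)
    if has_header:
        labels = tuple(tokens)
        data = np.loadtxt(path, delimiter=delim, skiprows=1)
    else:
        labels = ()
        data = np.loadtxt(path, delimiter=delim)
    return Connectome(weights=np.atleast_2d(data), labels=labels)


def write_connectome(connectome: Connectome, path: str | Path) -> None:
    path = Path(path)
    header = ",".join(connectome.labels)
    np.savetxt(path, connectome.weights, delimiter=",", header=header, comments="")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_receptor_map(
    path: str | Path, labels: tuple[str, ...] | None = None
) -> ReceptorMap:
    """Load densities from a 2-column TSV (label, density) or a 1-column file.

    With a two-column file and known region ``labels``, rows are reordered to
    match the connectome's label order.
    """
    path = Path(path)
    try:
        values = np.loadtxt(path)
        return ReceptorMap(density=values)
    except ValueError:
        pass
    df = pd.read_csv(path, sep="\t", header=None, names=["region", "density"])
    if labels is not None:
        missing = set(labels) - set(df["region"])
        if missing:
            raise InvalidParameterError(
                f"receptor map lacks regions: {sorted(missing)[:5]}"
            )
        df = df.set_index("region").loc[list(labels)].reset_index()
    return ReceptorMap(density=df["density"].to_numpy())


def write_receptor_map(
    receptors: ReceptorMap, path: str | Path, labels: tuple[str, ...] | None = None
) -> None:
    path = Path(path)
    if labels is None:
        np.savetxt(path, receptors.density)
    else:
        pd.DataFrame({"region": labels, "density": receptors.density}).to_csv(
            path, sep="\t", header=False, index=False
        )


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "region" not in df.columns:
        raise InvalidParameterError("metadata TSV must have a 'region' column")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_params(path: str | Path) -> ModelParameters:
    """Model parameters from a flat JSON object of field overrides."""
    with open(path) as fh:
        overrides = json.load(fh)
    valid = set(ModelParameters.__dataclass_fields__)
    unknown = set(overrides) - valid
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    return ModelParameters(**overrides)


def write_params(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
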