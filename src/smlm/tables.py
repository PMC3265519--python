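"""Molecule lists: the tabular output of an SMLM experiment.

One row per fitted switching event. Coordinates are continuous, in nm, with
the origin at the field-of-view corner; the center of camera pixel (0, 0)
sits at (0.5 px, 0.5 px) = (0.5, 0.5) * pixel_size nm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "CHANNELS", "LocalizationTable", "read_molecule_list", "write_molecule_list"]

COLUMNS = [
    "frame", "x_nm", "y_nm", "z_nm", "photons",
    "wx_nm", "wy_nm", "residual", "channel", "fov_id", "pass_id",
]

#: specific activator channels (by activation laser wavelength) plus sentinels
CHANNELS = ("ch405", "ch457", "ch532", "nonspecific", "unassigned")

_HEADER_COMMENT = (
    "# smlm molecule list; coordinates in nm, origin at FOV corner; "
    "pixel (0,0) center at (0.5 px, 0.5 px)"
)


def empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS,
        [int, float, float, float, float, float, float, float, object, int, int],
    )})
    return df


@dataclass
class LocalizationTable:
    """A molecule list plus the acquisition metadata needed to use it.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns as in :data:`COLUMNS`. ``z_nm`` is NaN in 2D mode;
        ``channel`` is "unassigned" until color coding.
    pixel_size_nm : float
        Camera pixel size used for acquisition.
    n_frames : int
        Movie length in frames (needed for drift binning and color coding).
    metadata : dict
        Free-form provenance (seed, calibration id, stage counts...).
    """

    df: pd.DataFrame
    pixel_size_nm: float = 160.0
    n_frames: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        for c in missing:
            if c == "channel":
                self.df[c] = "unassigned"
            elif c in ("fov_id", "pass_id", "frame"):
                self.df[c] = 0
            else:
                self.df[c] = np.nan
        extras = [c for c in self.df.columns if c not in COLUMNS]
        self.df = self.df[COLUMNS + extras].reset_index(drop=True)
        if self.n_frames == 0 and len(self.df):
            self.n_frames = int(self.df["frame"].max()) + 1

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(
            self.df.copy(), self.pixel_size_nm, self.n_frames, dict(self.metadata)
        )

    @classmethod
    def from_arrays(cls, x_nm, y_nm, frame, z_nm=None, photons=1000.0,
                    channel="unassigned", fov_id=0, pass_id=0, **kw) -> "LocalizationTable":
        n = len(np.atleast_1d(x_nm))
        df = pd.DataFrame({
            "frame": np.broadcast_to(np.asarray(frame, dtype=int), (n,)).copy(),
            "x_nm": np.asarray(x_nm, dtype=float),
            "y_nm": np.asarray(y_nm, dtype=float),
            "z_nm": (np.full(n, np.nan) if z_nm is None
                     else np.broadcast_to(np.asarray(z_nm, dtype=float), (n,)).copy()),
            "photons": np.broadcast_to(np.asarray(photons, dtype=float), (n,)).copy(),
            "channel": np.broadcast_to(np.asarray(channel, dtype=object), (n,)).copy(),
            "fov_id": np.broadcast_to(np.asarray(fov_id, dtype=int), (n,)).copy(),
            "pass_id": np.broadcast_to(np.asarray(pass_id, dtype=int), (n,)).copy(),
        })
        return cls(df, **kw)


def write_molecule_list(table: LocalizationTable, path) -> None:
    """Write a molecule list as commented CSV (nm units, see header)."""
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT + "\n")
        fh.write(f"# pixel_size_nm={table.pixel_size_nm} n_frames={table.n_frames}\n")
        table.df.to_csv(fh, index=False)


def read_molecule_list(path) -> LocalizationTable:
    pixel_size, n_frames = 160.0, 0
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("pixel_size_nm="):
                    pixel_size = float(tok.split("=", 1)[1])
                elif tok.startswith("n_frames="):
                    n_frames = int(tok.split("=", 1)[1])
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)))
    return LocalizationTable(df, pixel_size_nm=pixel_size, n_frames=n_frames)
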