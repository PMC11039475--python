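"""Ground-truth bookkeeping for generated phantoms.

The single integer label grid encodes every structure: 0 is parenchyma
(background tissue), small codes are the vessel systems, infarct *blobs*
(individual lesions, possibly members of a fused cluster) occupy a dedicated
code range, and microchannels another.  The accompanying tables record, per
blob and per channel, the quantities the analysis pipeline later has to
estimate — this is the scoring reference for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["LabelCodes", "PhantomTruth"]


class LabelCodes:
    PARENCHYMA = 0
    PORTAL = 1
    CENTRAL = 2
    SINUSOID = 3
    INFARCT_BASE = 10        # blob b -> INFARCT_BASE + b
    CHANNEL_BASE = 100000    # channel k -> CHANNEL_BASE + k


INFARCT_COLUMNS = ["infarct_id", "cluster_id", "origin_zone", "volume_um3",
                   "n_channels", "channel_diam_um"]
CHANNEL_COLUMNS = ["channel_id", "cluster_id", "diameter_um", "length_um"]


def _empty_infarct_table() -> pd.DataFrame:
    return pd.DataFrame(columns=INFARCT_COLUMNS).astype(
        {"infarct_id": int, "cluster_id": int, "origin_zone": int,
         "volume_um3": float, "n_channels": int, "channel_diam_um": float})


def _empty_channel_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CHANNEL_COLUMNS).astype(
        {"channel_id": int, "cluster_id": int, "diameter_um": float, "length_um": float})


@dataclass
class PhantomTruth:
    """Label grid plus per-structure ground-truth tables."""

    labels: np.ndarray                 # int32, (z, y, x)
    voxel_size_um: float
    day: str = "control"
    seed: int = 0
    infarct_table: pd.DataFrame = field(default_factory=_empty_infarct_table)
    channel_table: pd.DataFrame = field(default_factory=_empty_channel_table)

    # ---- masks -----------------------------------------------------------
    @property
    def portal_mask(self) -> np.ndarray:
        return self.labels == LabelCodes.PORTAL

    @property
    def central_mask(self) -> np.ndarray:
        return self.labels == LabelCodes.CENTRAL

    @property
    def sinusoid_mask(self) -> np.ndarray:
        return self.labels == LabelCodes.SINUSOID

    @property
    def vessel_mask(self) -> np.ndarray:
        """All vascular lumina (portal + central + sinusoid)."""
        return (self.labels >= LabelCodes.PORTAL) & (self.labels <= LabelCodes.SINUSOID)

    @property
    def infarct_mask(self) -> np.ndarray:
        return (self.labels >= LabelCodes.INFARCT_BASE) & (self.labels < LabelCodes.CHANNEL_BASE)

    @property
    def channel_mask(self) -> np.ndarray:
        return self.labels >= LabelCodes.CHANNEL_BASE

    @property
    def parenchyma_mask(self) -> np.ndarray:
        return self.labels == LabelCodes.PARENCHYMA

    def infarct_components(self) -> np.ndarray:
        """Label grid of fused *components*: each blob mapped to its cluster id.

        Blobs of a fused cluster overlap, so a cluster is one 26-connected
        component; its id is the cluster id shared by its member blobs.
        """
        out = np.zeros(self.labels.shape, dtype=np.int32)
        if len(self.infarct_table) == 0:
            return out
        m = self.infarct_mask
        blob = self.labels[m] - LabelCodes.INFARCT_BASE
        mapping = np.zeros(int(self.infarct_table["infarct_id"].max()) + 1, dtype=np.int32)
        for _, row in self.infarct_table.iterrows():
            mapping[int(row.infarct_id)] = int(row.cluster_id)
        out[m] = mapping[blob]
        return out

    def component_table(self) -> pd.DataFrame:
        """Per-component (cluster) ground truth: volume, confluence, channels."""
        if len(self.infarct_table) == 0:
            return pd.DataFrame(columns=["cluster_id", "n_blobs", "volume_um3",
                                         "confluent", "origin_zone", "n_channels"])
        g = self.infarct_table.groupby("cluster_id")
        out = pd.DataFrame({
            "n_blobs": g["infarct_id"].count(),
            "volume_um3": g["volume_um3"].sum(),
            "origin_zone": g["origin_zone"].first(),
            "n_channels": g["n_channels"].sum(),
        }).reset_index()
        out["confluent"] = out["n_blobs"] >= 2
        return out

    # ---- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / "labels.tif", self.labels.astype(np.int32))
        self.infarct_table.to_csv(d / "infarct_truth.csv", index=False)
        self.channel_table.to_csv(d / "channel_truth.csv", index=False)
        meta = {
            "voxel_size_um": self.voxel_size_um,
            "day": self.day,
            "seed": int(self.seed),
            "label_dictionary": {
                "parenchyma": LabelCodes.PARENCHYMA,
                "portal": LabelCodes.PORTAL,
                "central": LabelCodes.CENTRAL,
                "sinusoid": LabelCodes.SINUSOID,
                "infarct_base": LabelCodes.INFARCT_BASE,
                "channel_base": LabelCodes.CHANNEL_BASE,
            },
        }
        (d / "truth.json").write_text(json.dumps(meta, indent=1))
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "PhantomTruth":
        d = Path(directory)
        meta = json.loads((d / "truth.json").read_text())
        return cls(
            labels=tifffile.imread(d / "labels.tif"),
            voxel_size_um=meta["voxel_size_um"],
            day=meta["day"],
            seed=meta["seed"],
            infarct_table=pd.read_csv(d / "infarct_truth.csv"),
            channel_table=pd.read_csv(d / "channel_truth.csv"),
        )
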