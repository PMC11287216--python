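"""End-to-end orchestration: QC → clustering → classification → profiles →
rates, with a run manifest recording every parameter and input digest."""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io
from .catalog import load_catalog
from .classify import call_otu_guild
from .clustering import cluster_otus, qc_filter
from .geochem import (
    DEFAULT_LABEL_UMOL,
    DEFAULT_PKA,
    DEFAULT_SPECIFIC_ACTIVITY,
    process_porewater,
)
from .profiles import profile_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Pipeline failure; carries the name of the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineParams:
    """All tunables; everything here lands in the run manifest."""

    min_completeness: float = 50.0
    max_contamination: float = 10.0
    ani_threshold_pct: float = 95.0
    ani_symmetrize: str = "mean"
    min_display_pct: float = 2.0
    pka: float = DEFAULT_PKA
    specific_activity: float = DEFAULT_SPECIFIC_ACTIVITY
    label_added_umol: float = DEFAULT_LABEL_UMOL
    porewater_volume_mL: float = 10.0
    normalize_profiles: bool = True
    catalog_path: str | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PipelineResult:
    outdir: Path
    otus: list = field(default_factory=list)
    calls: dict = field(default_factory=dict)
    profiles = None
    rates = None


def run_all(
    mags_path,
    ani_path,
    markers_path,
    porewater_path=None,
    outdir="sedguilds_out",
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Execute the full pipeline on file inputs, writing all tables plus a
    manifest to ``outdir``. On failure, partial outputs are retained next to
    a ``.partial`` marker and a :class:`StageError` names the stage."""
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partial_marker = outdir / ".partial"
    partial_marker.write_text("pipeline running\n")
    result = PipelineResult(outdir=outdir)
    stage = "setup"
    try:
        stage = "load_inputs"
        mags = io.read_mags(mags_path)
        ani = io.read_ani(ani_path)
        marker_sets = io.read_markers(markers_path)
        catalog = (
            load_catalog(Path(params.catalog_path).read_text())
            if params.catalog_path
            else load_catalog()
        )
        for m in mags:
            object.__setattr__(m, "markers", marker_sets.get(m.mag_id, frozenset()))

        stage = "qc_filter"
        retained, rejected = qc_filter(
            mags, params.min_completeness, params.max_contamination
        )
        logger.info("QC: retained %d MAGs, rejected %d", len(retained), len(rejected))

        stage = "cluster_otus"
        depths = sorted({m.depth_cm for m in retained})
        otus = cluster_otus(
            ani,
            retained,
            threshold_pct=params.ani_threshold_pct,
            symmetrize=params.ani_symmetrize,
            depths=depths,
        )
        result.otus = otus
        io.write_otus(otus, outdir / "otus.tsv")
        logger.info("clustering: %d OTUs from %d MAGs", len(otus), len(retained))

        stage = "classify"
        calls = {
            otu.otu_id: call_otu_guild(otu, marker_sets, catalog) for otu in otus
        }
        result.calls = calls
        io.write_calls(calls, outdir / "guild_calls.tsv")
        io.write_json(
            {oid: c.evidence for oid, c in calls.items()}, outdir / "evidence.json"
        )

        stage = "profile"
        profiles = profile_table(
            otus, calls, depths=depths, normalize=params.normalize_profiles
        )
        result.profiles = profiles
        io.write_table(profiles, outdir / "profiles.tsv")

        if porewater_path is not None:
            stage = "rates"
            rates = process_porewater(
                io.read_table(porewater_path),
                pka=params.pka,
                specific_activity=params.specific_activity,
                label_added_umol=params.label_added_umol,
                porewater_volume_mL=params.porewater_volume_mL,
            )
            result.rates = rates
            io.write_table(rates, outdir / "rates.tsv")

        stage = "manifest"
        manifest = {
            "tool": "sedguilds",
            "version": __version__,
            "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "parameters": params.as_dict(),
            "inputs": {
                str(p): io.file_digest(p)
                for p in (mags_path, ani_path, markers_path, porewater_path)
                if p is not None
            },
            "catalog_digest": __import__("hashlib").sha256(
                catalog.to_yaml().encode()
            ).hexdigest(),
            "n_mags_retained": len(retained),
            "n_mags_rejected": len(rejected),
            "n_otus": len(otus),
        }
        io.write_json(manifest, outdir / "manifest.json")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc
    partial_marker.unlink(missing_ok=True)
    return result
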