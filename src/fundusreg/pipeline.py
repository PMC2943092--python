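"""End-to-end orchestration: detection, graphing, matching, consensus, ICP.

``register_images`` runs the full chain on a pair of fundus images and
returns the recovered quadratic transform together with a registration
report; failures are caught per stage and attributed in the report
(``segmentation_failure`` / ``no_stable_structures`` / ``icp_divergence`` /
``undefined_cem``).  ``run_sweep`` reproduces the experiment harness:
seeded repeats over a grid of phantom structure-noise levels, reporting
matching recall (correct matches over reported correspondences) and, in
full mode, registration success and CEM statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time

import numpy as np
import yaml

from . import graph as graphmod
from . import matching as matchmod
from . import metrics as metricsmod
from . import phantom as phantommod
from . import vessels as vesselsmod
from .icp import IcpParams, icp as _run_icp
from .struct_sac import (HuberParams, StructSacParams,
                         struct_sac as _run_struct_sac)
from .errors import (EmptyGraphError, FundusRegError, IcpDivergenceError,
                     NoStableStructuresError, SegmentationFailure,
                     UndefinedCemError)
from .metrics import EvalParams, RegistrationReport
from .transforms import QuadraticTransform, SimilarityTransform

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    mf: vesselsmod.MatchedFilterParams = dataclasses.field(
        default_factory=vesselsmod.MatchedFilterParams)
    probe: vesselsmod.ProbeParams = dataclasses.field(
        default_factory=vesselsmod.ProbeParams)
    min_edge_px: float = 10.0
    matching: matchmod.MatchingParams = dataclasses.field(
        default_factory=matchmod.MatchingParams)
    sac: StructSacParams = dataclasses.field(
        default_factory=StructSacParams)
    icp: IcpParams = dataclasses.field(
        default_factory=IcpParams)
    eval: EvalParams = dataclasses.field(default_factory=EvalParams)
    preprocess: bool = True
    channel: str = "green"

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in sub.items():
                if k not in fields:
                    continue
                if isinstance(v, list):
                    v = tuple(v)
                if isinstance(v, dict) and dataclasses.is_dataclass(
                        fields[k].type if isinstance(fields[k].type, type)
                        else None):
                    v = build(fields[k].type, v)
                kwargs[k] = v
            return klass(**kwargs)

        cfg = cls()
        kwargs = {}
        mapping = {
            "mf": vesselsmod.MatchedFilterParams,
            "probe": vesselsmod.ProbeParams,
            "matching": matchmod.MatchingParams,
            "sac": StructSacParams,
            "icp": IcpParams,
            "eval": EvalParams,
        }
        for key, val in (d or {}).items():
            if key in mapping and isinstance(val, dict):
                if key == "sac" and "huber" in val and isinstance(
                        val["huber"], dict):
                    val = dict(val)
                    val["huber"] = HuberParams(**val["huber"])
                kwargs[key] = build(mapping[key], val)
            elif hasattr(cfg, key):
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


@dataclasses.dataclass
class RegistrationResult:
    transform: QuadraticTransform | None
    report: RegistrationReport
    similarity: SimilarityTransform | None = None
    correspondences: matchmod.CorrespondenceSet | None = None
    inliers: matchmod.CorrespondenceSet | None = None


# ---------------------------------------------------------------------------
# stage cache


def _config_hash(image: vesselsmod.FundusImage, cfg: PipelineConfig) -> str:
    block = json.dumps({"mf": dataclasses.asdict(cfg.mf),
                        "probe": dataclasses.asdict(cfg.probe),
                        "min_edge_px": cfg.min_edge_px,
                        "preprocess": cfg.preprocess}, sort_keys=True)
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(image.pixels).tobytes())
    h.update(block.encode())
    return h.hexdigest()


def extract(image: vesselsmod.FundusImage, cfg: PipelineConfig | None = None,
            cache_dir=None) -> tuple[vesselsmod.CenterlineImage,
                                     graphmod.VascularGraph]:
    """Centerline skeleton and pruned vascular graph of one image.

    With ``cache_dir`` set, results are cached keyed by a content hash of the
    image and the extraction config block, so sweeps re-run only downstream
    stages.
    """
    cfg = cfg or PipelineConfig()
    key = None
    if cache_dir is not None:
        cache_dir = pathlib.Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        key = _config_hash(image, cfg)
        gpath = cache_dir / f"{key}.graph.json"
        spath = cache_dir / f"{key}.skeleton.npy"
        if gpath.exists() and spath.exists():
            skel = vesselsmod.CenterlineImage(np.load(spath).astype(bool))
            return skel, graphmod.VascularGraph.load_json(gpath)
    try:
        skel = vesselsmod.extract_centerline(image, cfg.mf, cfg.probe,
                                             do_preprocess=cfg.preprocess)
        if not skel.mask.any():
            raise SegmentationFailure("empty skeleton")
        vsg = graphmod.build_graph(skel, cfg.min_edge_px)
    except EmptyGraphError as exc:
        raise SegmentationFailure(str(exc)) from exc
    if len(vsg.nodes) < 3:
        raise SegmentationFailure(f"only {len(vsg.nodes)} graph nodes")
    if key is not None:
        np.save(cache_dir / f"{key}.skeleton.npy", skel.mask)
        vsg.save_json(cache_dir / f"{key}.graph.json")
    return skel, vsg


# ---------------------------------------------------------------------------
# registration


def register_images(ref: vesselsmod.FundusImage,
                    float_image: vesselsmod.FundusImage,
                    cfg: PipelineConfig | None = None,
                    cache_dir=None) -> RegistrationResult:
    """Full graph-matching + ICP registration of a fundus image pair."""
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()

    def fail(exc: FundusRegError) -> RegistrationResult:
        log.warning("registration failed at stage %s: %s", exc.stage, exc)
        report = RegistrationReport(cem=None, ncc=None, nmi=None,
                                    success=False, overlap_pct=None,
                                    runtime_s=time.perf_counter() - t0,
                                    stage=exc.stage)
        return RegistrationResult(None, report)

    try:
        skel_ref, g_ref = extract(ref, cfg, cache_dir)
        skel_flo, g_flo = extract(float_image, cfg, cache_dir)
    except SegmentationFailure as exc:
        return fail(exc)

    matches, _soft = matchmod.match_graphs(g_ref, g_flo, cfg.matching)
    try:
        sac = _run_struct_sac(matches, g_ref, g_flo, cfg.sac)
    except NoStableStructuresError as exc:
        return fail(exc)

    ref_pts = skel_ref.points
    flo_pts = skel_flo.points
    try:
        result = _run_icp(flo_pts, ref_pts, sac.transform, cfg.icp)
    except IcpDivergenceError as exc:
        return fail(exc)

    try:
        report = metricsmod.evaluate(ref, float_image, ref_pts, flo_pts,
                                     result.transform, cfg.eval,
                                     runtime_s=time.perf_counter() - t0)
    except UndefinedCemError as exc:
        return fail(exc)
    report.n_correspondences = len(sac.inliers)
    return RegistrationResult(result.transform, report,
                              similarity=sac.transform,
                              correspondences=matches, inliers=sac.inliers)


def register(ref_path, float_path, cfg: PipelineConfig | None = None,
             cache_dir=None) -> RegistrationResult:
    """File-based wrapper around :func:`register_images`."""
    cfg = cfg or PipelineConfig()
    ref = vesselsmod.FundusImage.from_file(ref_path, channel=cfg.channel)
    flo = vesselsmod.FundusImage.from_file(float_path, channel=cfg.channel)
    log.info("resolved pipeline config: %s", json.dumps(cfg.to_dict()))
    return register_images(ref, flo, cfg, cache_dir=cache_dir)


# ---------------------------------------------------------------------------
# experiment harness


def matching_recall(pair: phantommod.PhantomPair,
                    matches: matchmod.CorrespondenceSet) -> float:
    """Correct matches over reported correspondences (0 when none reported)."""
    if len(matches) == 0:
        return 0.0
    truth = set(pair.true_correspondences)
    correct = sum(1 for a, b, _ in matches.pairs if (a, b) in truth)
    return correct / len(matches)


SWEEP_COLUMNS = ("structure_noise", "n_runs", "recall_mean", "recall_std",
                 "sac_success_rate", "cem_mean", "cem_std")


def run_sweep(noise_fractions, n_repeats: int = 10, seed: int = 0,
              base_spec: phantommod.PhantomSpec | None = None,
              cfg: PipelineConfig | None = None, mode: str = "matching",
              out_csv=None) -> list[dict]:
    """Seeded phantom sweep over structure-noise levels.

    ``matching`` mode matches ground-truth graphs directly (recall of the
    matcher plus STRUCT-SAC success); ``full`` mode additionally renders the
    pair, runs the whole registration and reports CEM statistics.  Rows of
    per-cell means/stds are returned and optionally written as CSV.
    """
    cfg = cfg or PipelineConfig()
    base = base_spec or phantommod.PhantomSpec()
    rows: list[dict] = []
    seeds = np.random.SeedSequence(seed).generate_state(
        max(len(list(noise_fractions)), 1) * n_repeats) % (2 ** 31)
    k = 0
    for frac in noise_fractions:
        recalls, sac_ok, cems = [], [], []
        for _ in range(n_repeats):
            noise = dataclasses.replace(base.noise, structure_noise=float(frac))
            spec = dataclasses.replace(base, seed=int(seeds[k]), noise=noise)
            k += 1
            if mode == "matching":
                pair = phantommod.make_graph_pair(spec)
                matches, _ = matchmod.match_graphs(pair.graph_ref,
                                                   pair.graph_float,
                                                   cfg.matching)
                recalls.append(matching_recall(pair, matches))
                try:
                    _run_struct_sac(matches, pair.graph_ref,
                                    pair.graph_float, cfg.sac)
                    sac_ok.append(1.0)
                except (NoStableStructuresError, FundusRegError):
                    sac_ok.append(0.0)
            elif mode == "full":
                pair = phantommod.make_pair(spec)
                matches, _ = matchmod.match_graphs(pair.graph_ref,
                                                   pair.graph_float,
                                                   cfg.matching)
                recalls.append(matching_recall(pair, matches))
                res = register_images(pair.image_ref, pair.image_float, cfg)
                sac_ok.append(1.0 if res.report.stage == "ok" else 0.0)
                if res.report.cem is not None:
                    cems.append(res.report.cem)
            else:
                raise ValueError(f"unknown sweep mode {mode!r}")
        rows.append({
            "structure_noise": float(frac),
            "n_runs": n_repeats,
            "recall_mean": float(np.mean(recalls)) if recalls else float("nan"),
            "recall_std": float(np.std(recalls)) if recalls else float("nan"),
            "sac_success_rate": float(np.mean(sac_ok)) if sac_ok else float("nan"),
            "cem_mean": float(np.mean(cems)) if cems else float("nan"),
            "cem_std": float(np.std(cems)) if cems else float("nan"),
        })
    if out_csv is not None:
        write_sweep_csv(out_csv, rows)
    return rows


def write_sweep_csv(path, rows: list[dict]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=SWEEP_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k) for k in SWEEP_COLUMNS})
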