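"""Contour file I/O, printed-table fixtures, and the end-to-end pipeline.

Contour files come in two equivalent dialects:

* JSON -- a list of pullback documents ``{patient_id, timepoint, modality,
  slices: [{slice_id, myocardium_angle_deg, lumen: [[x, y], ...], wall: ...,
  lipids: [[[x, y], ...], ...]}]}``;
* flat CSV -- one row per contour point with columns ``patient_id, timepoint,
  modality, slice_id, myocardium_angle_deg, role, lipid_idx, pt_idx, x_mm,
  y_mm``.

Both round-trip to the same in-memory cohort; JSON written by this module is
byte-stable under read/write cycles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compare import (
    NoCapPointsError,
    PairedSliceMeasurement,
    PlaqueSet,
    paired_tests,
    summarize_table1,
    table1_stats,
)
from .geometry import ClosedContour, ContourError, SliceContours, validate_slice
from .quadrant import quantify_slice
from .vulnerability import (
    CapIndexConfusion,
    CapIndexScheme,
    DEFAULT_SCHEME,
    TrendRecord,
    assign_cap_index,
    classification_metrics,
    over_under_rates,
    trend_analysis,
)

logger = logging.getLogger("capquant")

_FIXTURES = ("table1", "table2", "table4")

_CSV_COLUMNS = [
    "patient_id",
    "timepoint",
    "modality",
    "slice_id",
    "myocardium_angle_deg",
    "role",
    "lipid_idx",
    "pt_idx",
    "x_mm",
    "y_mm",
]


class SchemaError(ValueError):
    """A contour file does not match the expected schema."""


class PipelineError(RuntimeError):
    """The analysis pipeline cannot produce a result (e.g. empty cohort)."""


@dataclass
class PullbackRecord:
    """All slices of one patient-timepoint pullback in one modality."""

    patient_id: str
    timepoint: str
    modality: str
    slices: list[SliceContours] = field(default_factory=list)


def _require(doc: dict, key: str, ctx: str):
    if key not in doc:
        raise SchemaError(f"{ctx}: missing field {key!r}")
    return doc[key]


def _parse_points(raw, ctx: str) -> np.ndarray:
    try:
        pts = np.asarray(raw, dtype=float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{ctx}: points must be numeric [[x, y], ...]") from exc
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise SchemaError(f"{ctx}: points must form an (n, 2) array")
    return pts


def _slice_from_doc(doc: dict, ctx: str, validate: bool) -> SliceContours:
    slice_id = str(_require(doc, "slice_id", ctx))
    ctx = f"{ctx}, slice {slice_id!r}"
    angle_deg = float(_require(doc, "myocardium_angle_deg", ctx))
    try:
        slc = SliceContours(
            slice_id=slice_id,
            modality=str(doc.get("modality", "")),
            lumen=ClosedContour(_parse_points(_require(doc, "lumen", ctx), f"{ctx}, lumen"), "lumen"),
            wall=ClosedContour(_parse_points(_require(doc, "wall", ctx), f"{ctx}, wall"), "wall"),
            lipids=tuple(
                ClosedContour(_parse_points(lp, f"{ctx}, lipid[{i}]"), "lipid")
                for i, lp in enumerate(doc.get("lipids", []))
            ),
            myocardium_angle=float(np.deg2rad(angle_deg)),
        )
        return validate_slice(slc) if validate else slc
    except ContourError as exc:
        raise type(exc)(f"{ctx}: {exc}") from exc


def read_contours(path, *, validate: bool = True) -> list[PullbackRecord]:
    """Read a JSON or CSV contour file into validated pullback records."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_contours_csv(path, validate)
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    if isinstance(payload, dict):
        payload = [payload]
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: expected a pullback document or list of them")
    records = []
    for d, doc in enumerate(payload):
        ctx = f"{path} document {d}"
        rec = PullbackRecord(
            patient_id=str(_require(doc, "patient_id", ctx)),
            timepoint=str(_require(doc, "timepoint", ctx)),
            modality=str(_require(doc, "modality", ctx)),
        )
        for sdoc in _require(doc, "slices", ctx):
            slc = _slice_from_doc({**sdoc, "modality": rec.modality}, ctx, validate)
            rec.slices.append(slc)
        records.append(rec)
    return records


def write_contours(records: Sequence[PullbackRecord], path) -> None:
    """Write pullback records in the JSON dialect (byte-stable round trips)."""
    payload = []
    for rec in records:
        payload.append(
            {
                "patient_id": rec.patient_id,
                "timepoint": rec.timepoint,
                "modality": rec.modality,
                "slices": [
                    {
                        "slice_id": s.slice_id,
                        # 12-decimal quantization keeps deg->rad->deg write
                        # cycles byte-stable (error ~1e-14 rad).
                        "myocardium_angle_deg": round(float(np.rad2deg(s.myocardium_angle)), 12),
                        "lumen": s.lumen.points.tolist(),
                        "wall": s.wall.points.tolist(),
                        "lipids": [lp.points.tolist() for lp in s.lipids],
                    }
                    for s in rec.slices
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def write_contours_csv(records: Sequence[PullbackRecord], path) -> None:
    """Write pullback records in the flat one-row-per-point CSV dialect."""
    rows = []
    for rec in records:
        for s in rec.slices:
            contours = [("lumen", -1, s.lumen), ("wall", -1, s.wall)] + [
                ("lipid", i, lp) for i, lp in enumerate(s.lipids)
            ]
            for role, lidx, contour in contours:
                for p, (x, y) in enumerate(contour.points):
                    rows.append(
                        (
                            rec.patient_id,
                            rec.timepoint,
                            rec.modality,
                            s.slice_id,
                            round(float(np.rad2deg(s.myocardium_angle)), 12),
                            role,
                            lidx,
                            p,
                            x,
                            y,
                        )
                    )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def _read_contours_csv(path: Path, validate: bool) -> list[PullbackRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing CSV columns {missing}")
    records = []
    for (pat, tp, mod), group in df.groupby(
        ["patient_id", "timepoint", "modality"], sort=True
    ):
        rec = PullbackRecord(str(pat), str(tp), str(mod))
        for slice_id, sgroup in group.groupby("slice_id", sort=True):
            ctx = f"{path}, slice {slice_id!r}"

            def contour_of(sub: pd.DataFrame, role: str) -> ClosedContour:
                sub = sub.sort_values("pt_idx")
                return ClosedContour(sub[["x_mm", "y_mm"]].to_numpy(float), role)

            lumen_rows = sgroup[sgroup["role"] == "lumen"]
            wall_rows = sgroup[sgroup["role"] == "wall"]
            if lumen_rows.empty or wall_rows.empty:
                raise SchemaError(f"{ctx}: needs both lumen and wall points")
            lipids = []
            lipid_rows = sgroup[sgroup["role"] == "lipid"]
            for lidx, lgroup in lipid_rows.groupby("lipid_idx", sort=True):
                lipids.append(contour_of(lgroup, "lipid"))
            try:
                slc = SliceContours(
                    slice_id=str(slice_id),
                    modality=rec.modality,
                    lumen=contour_of(lumen_rows, "lumen"),
                    wall=contour_of(wall_rows, "wall"),
                    lipids=tuple(lipids),
                    myocardium_angle=float(
                        np.deg2rad(sgroup["myocardium_angle_deg"].iloc[0])
                    ),
                )
                rec.slices.append(validate_slice(slc) if validate else slc)
            except ContourError as exc:
                raise type(exc)(f"{ctx}: {exc}") from exc
        records.append(rec)
    return records


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the shipped printed-table fixtures.

    ``table1``: per-plaque mean/min cap thickness (mm) in both modalities with
    the published relative-error columns.  ``table2``: cap-index confusion
    counts (OCT reference rows, IVUS columns).  ``table4``: per-patient plaque
    cap indices at baseline and follow-up in both modalities.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    with resources.files("capquant").joinpath(f"fixtures/{name}.csv").open() as fh:
        return pd.read_csv(fh)


def confusion_from_table2(df: Optional[pd.DataFrame] = None) -> CapIndexConfusion:
    """Build the 4x4 cap-index confusion from a table2-shaped count frame."""
    if df is None:
        df = load_fixture("table2")
    counts = np.zeros((4, 4), dtype=int)
    for _, row in df.iterrows():
        r = int(row["oct_index"]) - 1
        counts[r] = [row["ivus_1"], row["ivus_2"], row["ivus_3"], row["ivus_4"]]
    conf = CapIndexConfusion(counts)
    if not np.array_equal(conf.row_totals, df.set_index("oct_index")["n_slices"].to_numpy()):
        raise SchemaError("table2 row sums do not match the n_slices column")
    return conf


def trend_from_table4(df: Optional[pd.DataFrame] = None) -> tuple[pd.DataFrame, float]:
    """Trend analysis (delta indices, agreement rate) from a table4 frame."""
    if df is None:
        df = load_fixture("table4")
    records = [
        TrendRecord(
            patient_id=str(row["patient"]),
            oct_t1=int(row["oct_t1"]),
            oct_t2=int(row["oct_t2"]),
            ivus_t1=int(row["ivus_t1"]),
            ivus_t2=int(row["ivus_t2"]),
        )
        for _, row in df.iterrows()
    ]
    return trend_analysis(records)


def reproduce_tables() -> dict:
    """Fixtures-only reproduction of every table-derived rate.

    Runs with zero geometry: the printed per-plaque summary, confusion counts
    and trend indices are the inputs; all derived statistics (averages,
    relative errors, disagreement and over/under-estimation rates, prediction
    metrics, trend agreement) are recomputed from them.
    """
    t1 = table1_stats(load_fixture("table1"))

    conf = confusion_from_table2()
    metrics = classification_metrics(conf)
    overall = over_under_rates(conf)
    restricted = over_under_rates(conf, restrict_to=(2, 3))
    group_dis = conf.group_disagreement()

    trend_df, agreement = trend_from_table4()

    return {
        "table1": t1,
        "table2": {
            "n_slices": conf.total,
            "group_disagreement_pct": [
                None if np.isnan(g) else 100 * g for g in group_dis
            ],
            "overall_disagreement_pct": 100 * conf.overall_disagreement(),
            "restricted_disagreement_pct": 100 * (1 - restricted["agree"]),
            "over_pct": 100 * overall["over"],
            "under_pct": 100 * overall["under"],
            "over_restricted_pct": 100 * restricted["over"],
            "under_restricted_pct": 100 * restricted["under"],
        },
        "table3": {
            f"index{k}": {
                col.replace("_pct", ""): (None if np.isnan(v) else float(v))
                for col, v in metrics.loc[k].items()
            }
            for k in (1, 2, 3, 4)
        },
        "table4": {
            "n_patients": len(trend_df),
            "agreement_pct": 100 * agreement,
            "delta_oct": trend_df["delta_oct"].tolist(),
            "delta_ivus": trend_df["delta_ivus"].tolist(),
        },
    }


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    inputs: tuple = ()
    output_dir: str = "capquant_out"
    scheme: CapIndexScheme = DEFAULT_SCHEME
    seed: int = 0
    fixtures_only: bool = False
    n_points: int = 100


def _pair_slices(
    records: Sequence[PullbackRecord],
) -> dict:
    """Group slices as (patient, timepoint, slice_id) -> {modality: slice}."""
    paired: dict = {}
    for rec in records:
        for slc in rec.slices:
            key = (rec.patient_id, rec.timepoint, slc.slice_id)
            paired.setdefault(key, {})[rec.modality.upper()] = slc
    return paired


def run_pipeline(config: RunConfig) -> dict:
    """Quantify -> compare -> index -> trend, writing a report bundle.

    Returns a dict of output paths and headline numbers.  In fixtures-only
    mode the geometry stages are skipped and the printed-table statistics are
    recomputed and written.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.fixtures_only:
        results = reproduce_tables()
        (outdir / "summary.json").write_text(json.dumps(results, indent=2) + "\n")
        return {"summary": results, "outputs": [str(outdir / "summary.json")]}

    t0 = time.perf_counter()
    records = []
    for p in config.inputs:
        records.extend(read_contours(p))
    paired = _pair_slices(records)
    if not paired:
        raise PipelineError("empty cohort: no slices found in the inputs")

    pairs: dict = {}
    excluded_unpaired = 0
    for (pat, tp, sid), by_mod in sorted(paired.items()):
        if "OCT" not in by_mod or "IVUS" not in by_mod:
            excluded_unpaired += 1
            continue
        pairs[(pat, tp, sid)] = PairedSliceMeasurement(
            slice_id=sid,
            oct=quantify_slice(by_mod["OCT"], n_points=config.n_points, validate=False),
            ivus=quantify_slice(by_mod["IVUS"], n_points=config.n_points, validate=False),
        )
    if not pairs:
        raise PipelineError("no co-registered OCT/IVUS slice pairs in the inputs")
    logger.info(
        "quantified %d slice pairs in %.1f s (%d unpaired slices excluded)",
        len(pairs), time.perf_counter() - t0, excluded_unpaired,
    )

    plaques: dict = {}
    for (pat, tp, sid), pm in pairs.items():
        plaques.setdefault((pat, tp), PlaqueSet(pat, tp)).slices.append(pm)

    # Per-point measurement and scatter tables.
    point_frames, scatter_rows = [], []
    for (pat, tp, sid), pm in pairs.items():
        for prof in (pm.oct, pm.ivus):
            frame = prof.to_frame()
            frame.insert(0, "patient_id", pat)
            frame.insert(1, "timepoint", tp)
            point_frames.append(frame)
        for i in pm.matched_cap_indices:
            scatter_rows.append(
                (pat, tp, sid, int(i), pm.oct.cap_thickness[i], pm.ivus.cap_thickness[i])
            )
    measurements = pd.concat(point_frames, ignore_index=True)
    scatter = pd.DataFrame(
        scatter_rows,
        columns=["patient_id", "timepoint", "slice_id", "pt_idx", "capt_oct_mm", "capt_ivus_mm"],
    )

    usable = [p for p in plaques.values() if p.all_diffs().size > 0]
    excluded_plaques = len(plaques) - len(usable)
    if not usable:
        raise PipelineError("no plaque has matched cap points")
    table1_df, cohort = summarize_table1(usable)

    tests = (
        paired_tests(table1_df["mean_capt_oct_mm"], table1_df["mean_capt_ivus_mm"])
        if len(table1_df) >= 3
        else None
    )

    # Slice-level cap-index confusion (index-0 slices excluded by default).
    ref_idx, test_idx, n_index0 = [], [], 0
    for pm in pairs.values():
        io_, ii = pm.oct.min_cap(), pm.ivus.min_cap()
        r = assign_cap_index(io_, config.scheme)
        t = assign_cap_index(ii, config.scheme)
        if r == 0 or t == 0:
            n_index0 += 1
            continue
        ref_idx.append(r)
        test_idx.append(t)
    confusion = CapIndexConfusion.from_indices(ref_idx, test_idx) if ref_idx else None

    # Trend: needs both timepoints per patient.
    min_cap_rows = []
    patients = sorted({pat for pat, _ in plaques})
    for pat in patients:
        row: dict = {"patient_id": pat}
        for tp in ("T1", "T2"):
            plq = plaques.get((pat, tp))
            for modality in ("oct", "ivus"):
                key = f"{modality}_{tp.lower()}_mm"
                if plq is None:
                    row[key] = None
                else:
                    caps = plq.cap_values(modality.upper())
                    row[key] = float(caps.min()) if caps.size else np.nan
        min_cap_rows.append(row)
    trend_records = [
        TrendRecord(
            patient_id=row["patient_id"],
            oct_t1=assign_cap_index(_none_if_nan(row["oct_t1_mm"]), config.scheme),
            oct_t2=assign_cap_index(_none_if_nan(row["oct_t2_mm"]), config.scheme),
            ivus_t1=assign_cap_index(_none_if_nan(row["ivus_t1_mm"]), config.scheme),
            ivus_t2=assign_cap_index(_none_if_nan(row["ivus_t2_mm"]), config.scheme),
        )
        for row in min_cap_rows
        if all(row[k] is not None for k in list(row)[1:])
    ]
    trend_df, agreement = (
        trend_analysis(trend_records) if trend_records else (None, np.nan)
    )

    # Write the bundle.
    outputs = {}
    measurements.to_csv(outdir / "measurements.csv", index=False)
    scatter.to_csv(outdir / "scatter.csv", index=False)
    table1_df.to_csv(outdir / "table1_summary.csv", index=False)
    outputs["measurements"] = str(outdir / "measurements.csv")
    outputs["scatter"] = str(outdir / "scatter.csv")
    outputs["table1_summary"] = str(outdir / "table1_summary.csv")
    if confusion is not None:
        pd.DataFrame(
            confusion.counts,
            index=[f"oct_{k}" for k in range(1, 5)],
            columns=[f"ivus_{k}" for k in range(1, 5)],
        ).to_csv(outdir / "confusion.csv")
        classification_metrics(confusion).to_csv(outdir / "metrics.csv")
        outputs["confusion"] = str(outdir / "confusion.csv")
        outputs["metrics"] = str(outdir / "metrics.csv")
    if trend_df is not None:
        trend_df.to_csv(outdir / "trend.csv", index=False)
        outputs["trend"] = str(outdir / "trend.csv")

    summary = {
        "n_slice_pairs": len(pairs),
        "n_plaques": len(plaques),
        "n_plaques_with_matched_caps": len(usable),
        "excluded_unpaired_slices": excluded_unpaired,
        "excluded_plaques_no_caps": excluded_plaques,
        "excluded_index0_slices": n_index0,
        "cohort": cohort,
        "paired_tests_mean_capt": tests,
        "overall_index_disagreement_pct": (
            100 * confusion.overall_disagreement() if confusion is not None else None
        ),
        "trend_agreement_pct": (
            None if trend_df is None else 100 * agreement
        ),
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    outputs["summary"] = str(outdir / "summary.json")
    return {"summary": summary, "outputs": outputs}


def _none_if_nan(v):
    if v is None:
        return None
    return None if isinstance(v, float) and np.isnan(v) else float(v)
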