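"""End-to-end orchestration: CSP → accessibility → docking contacts →
conservation → combined per-residue report.

The pipeline reads a YAML/dict configuration naming the input files and the
analysis parameters (CSP significance threshold, nitrogen weight, contact
cutoff, CDR definition, region scheme), runs the stages in dependency order,
and writes a TSV bundle plus a versioned JSON report.  Stages whose inputs
are absent from the configuration (e.g. no structure, no pose ensemble) are
skipped with a warning; the report keeps their fields as null so the schema
is stable.  Given fixed inputs the outputs are byte-identical across reruns:
floats are formatted to 6 significant digits and no timestamps enter any
artifact except the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import conservation as cons
from . import docking as dock
from . import nmr_csp as csp_mod
from . import structure as struct_mod

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; paths are resolved against ``base_dir``."""

    free_shifts: Path
    titration: list[dict[str, Any]]  # {shifts, concentration_uM, ratio}
    out_dir: Path
    decays: dict[str, dict[str, Path]] | None = None
    structure: Path | None = None
    poses: Path | None = None
    pose_scores: Path | None = None
    antigen_chain: str = "A"
    antibody_chain: str = "B"
    cdr: list[int] | None = None
    alignment: Path | None = None
    reference_id: str | None = None
    literature_epitopes: Path | None = None
    csp_threshold: float = 0.028
    nitrogen_weight: float = 0.1
    contact_cutoff: float = 5.0
    score_top_fraction: float = 1.0
    docking_freq_threshold: float = 0.5
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(csp_mod.DEFAULT_REGION_SCHEME)
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("csp_threshold", "nitrogen_weight", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.titration:
            raise ValueError("at least one titration point is required")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=path.parent, out_dir=out_dir)

    @classmethod
    def from_dict(
        cls, raw: dict[str, Any], base_dir: str | Path, out_dir: str | Path
    ) -> "PipelineConfig":
        base = Path(base_dir)

        def resolve(p: str | None) -> Path | None:
            return None if p is None else (base / p)

        decays = None
        if raw.get("decays"):
            decays = {
                state: {mode: base / p for mode, p in modes.items()}
                for state, modes in raw["decays"].items()
            }
        regions = {
            name: tuple(iv) for name, iv in raw.get(
                "regions", csp_mod.DEFAULT_REGION_SCHEME
            ).items()
        }
        return cls(
            free_shifts=base / raw["free_shifts"],
            titration=raw["titration"],
            out_dir=Path(out_dir),
            decays=decays,
            structure=resolve(raw.get("structure")),
            poses=resolve(raw.get("poses")),
            pose_scores=resolve(raw.get("pose_scores")),
            antigen_chain=raw.get("antigen_chain", "A"),
            antibody_chain=raw.get("antibody_chain", "B"),
            cdr=raw.get("cdr"),
            alignment=resolve(raw.get("alignment")),
            reference_id=raw.get("reference_id"),
            literature_epitopes=resolve(raw.get("literature_epitopes")),
            csp_threshold=float(raw.get("csp_threshold", 0.028)),
            nitrogen_weight=float(raw.get("nitrogen_weight", 0.1)),
            contact_cutoff=float(raw.get("contact_cutoff", 5.0)),
            score_top_fraction=float(raw.get("score_top_fraction", 1.0)),
            docking_freq_threshold=float(raw.get("docking_freq_threshold", 0.5)),
            regions=regions,
            log_level=raw.get("log_level", "INFO"),
        )

    def parameters(self) -> dict[str, Any]:
        return {
            "csp_threshold": self.csp_threshold,
            "nitrogen_weight": self.nitrogen_weight,
            "contact_cutoff": self.contact_cutoff,
            "score_top_fraction": self.score_top_fraction,
            "docking_freq_threshold": self.docking_freq_threshold,
            "regions": {k: list(v) for k, v in self.regions.items()},
        }


@dataclass
class AnalysisReport:
    """Joined result of all stages; serialisable to/from JSON."""

    schema_version: str
    parameters: dict[str, Any]
    csp_epitope: list[int] | None
    docking_epitope: list[int] | None
    literature_epitopes: list[dict[str, Any]] | None
    disappeared: list[int]
    region_counts: dict[str, int]
    region_unassigned: list[int]
    per_point_significant: dict[str, list[int]]
    jaccard_csp_docking: float | None
    relaxation_summary: dict[str, float] | None
    per_residue: list[dict[str, Any]]
    overlap_report: list[dict[str, Any]] | None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisReport":
        with open(path) as fh:
            return cls(**json.load(fh))

    def per_residue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_residue)


def _jaccard(a: set[int], b: set[int]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def _fmt(v: Any) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run every configured stage and write all artifacts into ``out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("parvmap")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())
    try:
        return _run(config)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig) -> AnalysisReport:
    out = config.out_dir
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                **config.parameters(),
                "inputs": {
                    "free_shifts": str(config.free_shifts),
                    "titration": config.titration,
                    "structure": str(config.structure) if config.structure else None,
                    "poses": str(config.poses) if config.poses else None,
                    "alignment": str(config.alignment) if config.alignment else None,
                },
            },
            fh,
            sort_keys=True,
        )

    # --- stage: CSP ---------------------------------------------------------
    logger.info("stage csp: reading shift tables")
    try:
        free = csp_mod.read_shift_table(config.free_shifts, "free")
        base = config.free_shifts.parent
        points: list[tuple[float, csp_mod.ShiftTable]] = []
        for entry in config.titration:
            table = csp_mod.read_shift_table(
                base / entry["shifts"], Path(entry["shifts"]).stem
            )
            points.append((float(entry["concentration_uM"]), table))
    except Exception as exc:
        raise RuntimeError(f"stage 'csp' failed: {exc}") from exc

    scheme = csp_mod.RegionScheme(regions=config.regions)
    per_point_significant: dict[str, list[int]] = {}
    headline_records: list[csp_mod.CSPRecord] | None = None
    headline_label = ""
    for conc, table in sorted(points, key=lambda p: p[0]):
        records = csp_mod.compute_csp(free, table, config.nitrogen_weight)
        epitope, _ = csp_mod.classify_perturbed(records, config.csp_threshold)
        significant = epitope.sorted() if epitope else []
        per_point_significant[table.state_label] = significant
        csp_mod.write_csp_table(
            records, set(significant), out / f"csp_{table.state_label}.tsv"
        )
        headline_records, headline_label = records, table.state_label

    assert headline_records is not None
    csp_epitope, disappeared = csp_mod.classify_perturbed(
        headline_records, config.csp_threshold
    )
    if csp_epitope is None:
        region_counts = {name: 0 for name in scheme.regions}
        unassigned: list[int] = []
    else:
        region_counts, unassigned = csp_mod.segment_regions(csp_epitope, scheme)
    logger.info(
        "stage csp: %d significant residues at point %s, %d disappeared",
        len(csp_epitope.residues) if csp_epitope else 0, headline_label, len(disappeared),
    )

    # --- stage: relaxation --------------------------------------------------
    relaxation_summary: dict[str, float] | None = None
    if config.decays:
        logger.info("stage relax: fitting decay series")
        try:
            summaries: dict[str, float] = {}
            for state, modes in config.decays.items():
                fits = {}
                for mode, path in modes.items():
                    df = pd.read_csv(path, sep="\t")
                    fits[mode] = csp_mod.fit_relaxation(df, mode)
                if {"R1", "R2"} <= set(fits):
                    records = csp_mod.relaxation_records(fits["R1"], fits["R2"])
                    ratios = [r.ratio_R2_over_R1 for r in records]
                    summaries[f"mean_R2_over_R1_{state}"] = (
                        float(pd.Series(ratios).mean()) if ratios else float("nan")
                    )
            relaxation_summary = summaries
        except Exception as exc:
            raise RuntimeError(f"stage 'relax' failed: {exc}") from exc
    else:
        logger.warning("stage relax: no decay series configured; skipped")

    # --- stage: structure / accessibility ------------------------------------
    accessibility: dict[int, struct_mod.AccessibilityRecord] = {}
    structure = None
    if config.structure:
        logger.info("stage sasa: computing accessibility")
        try:
            structure = struct_mod.read_structure(config.structure)
            chain_res = {
                r.number for r in structure.chain(config.antigen_chain)
            } if config.antigen_chain in structure.chains else {
                r.number for residues in structure.chains.values() for r in residues
            }
            table_res = {int(r) for r in free.residues}
            mismatched = sorted(table_res - chain_res)
            if mismatched:
                raise RuntimeError(
                    "residue numbering mismatch between shift table and structure; "
                    f"shift residues absent from structure: {mismatched}"
                )
            records = struct_mod.compute_sasa(structure)
            struct_mod.write_accessibility_table(records, out / "accessibility.tsv")
            accessibility = {r.residue_number: r for r in records}
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage 'sasa' failed: {exc}") from exc
    else:
        logger.warning("stage sasa: no structure configured; skipped")

    # --- stage: docking contacts ---------------------------------------------
    profile = None
    docking_epitope = None
    if config.poses:
        logger.info("stage contacts: profiling pose ensemble")
        try:
            ensemble = dock.read_pose_ensemble(
                config.poses,
                antigen_chain=config.antigen_chain,
                antibody_chain=config.antibody_chain,
                score_table=config.pose_scores,
            )
            if not config.cdr:
                raise ValueError("pose ensemble configured but no CDR definition given")
            cdr = dock.CDRDefinition(residues=frozenset(int(r) for r in config.cdr))
            profile = dock.contact_frequency(
                ensemble, cdr, config.contact_cutoff, config.score_top_fraction
            )
            dock.write_contact_table(profile, out / "contacts.tsv")
            ep = profile.epitope(config.docking_freq_threshold)
            docking_epitope = ep.sorted() if ep else []
        except Exception as exc:
            raise RuntimeError(f"stage 'contacts' failed: {exc}") from exc
    else:
        logger.warning("stage contacts: no pose ensemble configured; skipped")

    # --- stage: structure annotation -----------------------------------------
    if structure is not None and csp_epitope is not None:
        csp_scores = {
            r.residue_number: r.csp
            for r in headline_records
            if r.status is csp_mod.CSPStatus.MEASURED
        }
        struct_mod.annotate_structure(
            structure, csp_scores, out / "antigen_csp.pdb",
            chain_id=config.antigen_chain if config.antigen_chain in structure.chains else None,
        )
        if profile is not None:
            freq_scores = {
                int(r): float(f)
                for r, f in zip(profile.data["residue"], profile.data["frequency"])
            }
            struct_mod.annotate_structure(
                structure, freq_scores, out / "antigen_contact_freq.pdb",
                chain_id=config.antigen_chain if config.antigen_chain in structure.chains else None,
            )

    # --- stage: conservation --------------------------------------------------
    conservation_rows: dict[int, dict[str, Any]] = {}
    overlap_report = None
    literature_list = None
    if config.alignment and config.reference_id and csp_epitope is not None:
        logger.info("stage conserve: mapping epitope onto alignment")
        try:
            aln = cons.read_alignment(config.alignment)
            mapped = cons.map_epitope_columns(csp_epitope, config.reference_id, aln)
            mapped_out = mapped.copy()
            mapped_out["identical_fraction"] = mapped_out["identical_fraction"].map(
                lambda v: f"{v:.6g}"
            )
            mapped_out.to_csv(out / "epitope_conservation.tsv", sep="\t", index=False)
            conservation_rows = {
                int(row["residue"]): {
                    "symbol": row["symbol"],
                    "identical_fraction": float(row["identical_fraction"]),
                }
                for _, row in mapped.iterrows()
            }
            literature = (
                cons.read_literature_epitopes(config.literature_epitopes)
                if config.literature_epitopes
                else cons.PACKAGED_LITERATURE_EPITOPES
            )
            overlap = cons.epitope_overlap_report(csp_epitope, literature)
            overlap_out = overlap.copy()
            overlap_out["jaccard"] = overlap_out["jaccard"].map(lambda v: f"{v:.6g}")
            overlap_out.to_csv(out / "epitope_overlap.tsv", sep="\t", index=False)
            overlap_report = overlap.to_dict(orient="records")
            literature_list = [
                {"name": n, "start": s, "end": e, "source": src}
                for n, s, e, src in literature.intervals
            ]
        except Exception as exc:
            raise RuntimeError(f"stage 'conserve' failed: {exc}") from exc
    else:
        logger.warning("stage conserve: alignment or reference id missing; skipped")

    # --- combined per-residue table -------------------------------------------
    residues = sorted(
        {r.residue_number for r in headline_records}
        | set(accessibility)
        | (set(int(r) for r in profile.data["residue"]) if profile is not None else set())
    )
    csp_by_res = {r.residue_number: r for r in headline_records}
    sig_set = set(csp_epitope.residues) if csp_epitope else set()
    dock_set = set(docking_epitope or [])
    per_residue = []
    for res in residues:
        rec = csp_by_res.get(res)
        acc = accessibility.get(res)
        row = {
            "residue": res,
            "csp_ppm": rec.csp if rec and rec.csp is not None else None,
            "csp_status": rec.status.value if rec else None,
            "csp_significant": res in sig_set,
            "contact_frequency": profile.frequency_of(res) if profile is not None else None,
            "docking_epitope": res in dock_set if profile is not None else None,
            "rel_accessibility": acc.relative_accessibility if acc else None,
            "exposed": acc.exposed if acc else None,
            "conservation_symbol": conservation_rows.get(res, {}).get("symbol"),
            "identical_fraction": conservation_rows.get(res, {}).get("identical_fraction"),
        }
        per_residue.append(row)
    per_res_df = pd.DataFrame(per_residue)
    per_res_df_out = per_res_df.map(_fmt)
    per_res_df_out.to_csv(out / "residues.tsv", sep="\t", index=False)

    jaccard = (
        _jaccard(sig_set, dock_set) if csp_epitope is not None and profile is not None
        else None
    )

    report = AnalysisReport(
        schema_version=SCHEMA_VERSION,
        parameters=config.parameters(),
        csp_epitope=csp_epitope.sorted() if csp_epitope else None,
        docking_epitope=docking_epitope,
        literature_epitopes=literature_list,
        disappeared=disappeared,
        region_counts=region_counts,
        region_unassigned=unassigned,
        per_point_significant=per_point_significant,
        jaccard_csp_docking=jaccard,
        relaxation_summary=relaxation_summary,
        per_residue=per_residue,
        overlap_report=overlap_report,
    )
    report.to_json(out / "report.json")
    logger.info("pipeline complete: %d residues in combined table", len(per_residue))
    return report


def write_report(report: AnalysisReport, out_dir: str | Path, fmt: str = "json") -> list[Path]:
    """Re-emit a report as JSON or as a TSV bundle (per-residue + overlap tables)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = out_dir / "report.json"
        report.to_json(path)
        written.append(path)
    elif fmt == "tsv_bundle":
        per_res = report.per_residue_frame().map(_fmt)
        path = out_dir / "residues.tsv"
        per_res.to_csv(path, sep="\t", index=False)
        written.append(path)
        if report.overlap_report is not None:
            df = pd.DataFrame(report.overlap_report).map(_fmt)
            path = out_dir / "epitope_overlap.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
    else:
        raise ValueError("format must be 'json' or 'tsv_bundle'")
    return written
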