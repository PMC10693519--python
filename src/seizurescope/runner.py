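"""End-to-end pipeline runner with a reproducibility manifest.

``run_all`` executes (optionally) simulate -> conservation -> signals ->
burden -> integrate, writing every stage's outputs plus a JSON manifest
listing parameters, seeds and a SHA-256 hash of every output file.  Two
runs with the same config and seed reproduce every hash; only the manifest
timestamp differs.  Any stage failure aborts with a stage-named error and
leaves a FAILED marker next to the partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .alignments import read_alignment_fasta, read_annotation_tsv
from .conservation import ConservationModel
from .disproportionality import DisproportionalityModel, read_term_group
from .integrate import integrate_flags, read_hit_flags
from .matrices import build_custom_matrix, load_bundled_blosum90, load_raw_matrix
from .simulate import make_fixture_bundle

logger = logging.getLogger("seizurescope")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_logging(out_dir: Path, debug: bool = False) -> None:
    level = logging.DEBUG if debug else logging.INFO
    logger.setLevel(level)
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            h.close()
            logger.removeHandler(h)
    if not any(type(h) is logging.StreamHandler for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)


def run_all(
    out_dir: str | Path,
    simulate: bool = False,
    seed: int = 1,
    inputs: dict | None = None,
    prr_min: float = 2.0,
    min_reports: int = 5,
    k: int = 10,
    coverage: float = 0.98,
    make_plots: bool = True,
    debug: bool = False,
) -> dict:
    """Run the full pipeline; return the manifest dict.

    ``inputs`` maps stage inputs to paths (keys: ``alignments`` — a
    directory or list of FASTA files, ``annotations``, ``matrix``
    (optional; bundled BLOSUM90 by default), ``reports``, ``term_group``,
    ``hits``); with ``simulate=True`` a fixture bundle generated from
    ``seed`` supplies them all.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, debug)
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "simulate": simulate,
        "parameters": {
            "prr_min": prr_min,
            "min_reports": min_reports,
            "k": k,
            "coverage": coverage,
        },
        "stages": [],
        "outputs": {},
    }
    written: list[Path] = []

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        if simulate:
            stage("simulate")
            bundle_dir = out / "inputs"
            paths = make_fixture_bundle(bundle_dir, seed=seed)
            inputs = {
                "alignments": [paths["alignment"]],
                "annotations": paths["annotations"],
                "reports": paths["reports"],
                "term_group": paths["term_group"],
                "hits": paths["hits"],
            }
            written.extend(paths.values())
        if not inputs:
            raise ValueError("either supply inputs or pass simulate=True")

        try:
            stage("conservation")
            aln_spec = inputs["alignments"]
            if isinstance(aln_spec, (str, Path)) and Path(aln_spec).is_dir():
                fasta_paths = sorted(Path(aln_spec).glob("*.fasta"))
            else:
                fasta_paths = [Path(p) for p in aln_spec]
            alignments = {}
            for p in fasta_paths:
                aln = read_alignment_fasta(p)
                alignments[aln.subunit_id] = aln
            annotations = read_annotation_tsv(inputs["annotations"])
            raw = (
                load_raw_matrix(inputs["matrix"])
                if inputs.get("matrix")
                else load_bundled_blosum90()
            )
            matrix = build_custom_matrix(raw)
            cons = ConservationModel(
                alignments,
                matrix,
                annotations,
                reference_subunit_id=inputs.get("reference"),
            ).fit()
            cons_dir = out / "conservation"
            written.extend(cons.write_outputs(cons_dir))
            if make_plots:
                written.extend(cons.plot_tracks(cons_dir / "tracks"))
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError("conservation", exc) from exc

        try:
            stage("signals")
            model = DisproportionalityModel.from_tsv(
                inputs["reports"], term_group_path=inputs["term_group"]
            )
            results = model.fit(prr_min=prr_min, min_reports=min_reports)
            sig_dir = out / "signals"
            sig_dir.mkdir(exist_ok=True)
            written.append(results.write_signals_tsv(sig_dir / "signals.tsv"))
            (sig_dir / "summary.txt").write_text(results.summary() + "\n")
            written.append(sig_dir / "summary.txt")
        except Exception as exc:  # noqa: BLE001
            raise StageError("signals", exc) from exc

        try:
            stage("burden")
            burden = results.burden(k=k, coverage=coverage)
            bdir = out / "burden"
            bdir.mkdir(exist_ok=True)
            for name, frame in (
                ("pairs", burden.pair_table),
                ("drugs", burden.drug_table),
                ("ae_pie", burden.ae_pie),
            ):
                p = bdir / f"{name}.tsv"
                frame.to_csv(p, sep="\t", index=False, float_format="%.6f")
                written.append(p)
            rankings = {
                "group_total": burden.group_total,
                "top_coverage_terms": burden.top_coverage_terms,
                "top_by_burden": burden.top_by_burden,
                "top_by_pool_share": burden.top_by_pool_share,
                "intersection": sorted(burden.intersection),
            }
            p = bdir / "rankings.json"
            p.write_text(json.dumps(rankings, indent=2, sort_keys=True) + "\n")
            written.append(p)
        except Exception as exc:  # noqa: BLE001
            raise StageError("burden", exc) from exc

        try:
            stage("integrate")
            if inputs.get("hits"):
                hits = read_hit_flags(inputs["hits"])
                flags = integrate_flags(results, hits, k=k)
                p = out / "red_flags.tsv"
                flags.to_csv(p, sep="\t", index=False)
                written.append(p)
        except Exception as exc:  # noqa: BLE001
            raise StageError("integrate", exc) from exc

    except StageError as err:
        (out / "FAILED").write_text(f"{err.stage}: {err.cause}\n")
        logger.error("%s", err)
        raise

    for p in written:
        manifest["outputs"][str(Path(p).relative_to(out))] = _sha256(Path(p))
    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d outputs to %s", len(written), out)
    return manifest
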