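"""End-to-end pipeline runner driven by a single YAML config.

Stages run in a fixed order (filter -> annotate -> enrich -> histogram ->
overlap -> scan -> centrimo -> spamo -> discover); a stage whose inputs are
absent from the config is skipped and noted in the summary.  The summary
JSON echoes every parameter, records SHA-256 checksums of the inputs and
package/library versions, so a report is self-describing and re-runs with
identical inputs reproduce every non-timing field byte for byte.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path
from typing import Optional

import numpy as np
import scipy

from . import __version__, io
from .motifs import central_enrichment, discover, scan, spaced_pair
from .proximity import (
    DEFAULT_WINDOW,
    category_table,
    dedup_unique_tss,
    filter_against_control,
    genes_per_category,
    overlap_summary,
    peaks_per_gene,
    proximity_enrichment,
    tss_histogram,
)

DEFAULT_PARAMS = {
    "window": DEFAULT_WINDOW,
    "bin_width": 5_000,
    "central_width": 100,
    "max_gap": 10,
    "k_min": 6,
    "k_max": 8,
    "motif": "CTGGYAC",
    "peak_point": "midpoint",
    "merge_windows": False,
}


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages whose inputs are present; return the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    inputs = {
        k: config[k]
        for k in (
            "peaks", "control", "genes", "chrom_sizes",
            "peaks_b", "peaks_c", "sequences", "negative_sequences",
        )
        if config.get(k)
    }
    for key, path in inputs.items():
        if not Path(path).exists():
            raise StageError("inputs", FileNotFoundError(f"{key}: {path}"))

    t0 = time.time()
    summary: dict = {
        "parameters": params,
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in inputs.items()},
        "versions": {
            "peakprox": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "stages": {},
    }

    genome = None
    if "chrom_sizes" in inputs:
        genome = io.read_chrom_sizes(inputs["chrom_sizes"])

    peaks = None
    if "peaks" in inputs:
        try:
            peaks = io.read_bed(inputs["peaks"], genome=genome, label="treatment")
        except Exception as exc:  # noqa: BLE001 - report which stage failed
            raise StageError("annotate", exc) from exc

    # -- filter ------------------------------------------------------------
    if peaks is not None and "control" in inputs:
        try:
            control = io.read_bed(inputs["control"], genome=genome, label="control")
            retained, removed = filter_against_control(peaks, control)
            io.write_bed(retained, out / "peaks.retained.bed")
            io.write_bed(removed, out / "peaks.removed.bed")
            summary["stages"]["filter"] = {
                "treatment": len(peaks),
                "retained": len(retained),
                "removed": len(removed),
            }
            peaks = retained
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("filter", exc) from exc
    else:
        summary["stages"]["filter"] = "skipped (no control)"

    gene_lists = None
    if "genes" in inputs:
        gene_lists = io.read_gene_table(inputs["genes"])
        gene_lists = [dedup_unique_tss(gl) for gl in gene_lists]

    # -- annotate ----------------------------------------------------------
    if peaks is not None and gene_lists is not None:
        try:
            rows = []
            cats = {}
            for gl in gene_lists:
                ppg = peaks_per_gene(
                    peaks, gl, window=params["window"], peak_point=params["peak_point"]
                )
                for gene_id, n in ppg.per_gene.items():
                    rows.append({"list": gl.label, "gene_id": gene_id, "n_peaks": n})
                table = category_table(peaks, gl, window=params["window"])
                table.insert(0, "list", gl.label)
                cats[gl.label] = table
                summary["stages"].setdefault("annotate", {})[gl.label] = {
                    "tally": ppg.tally,
                    "distinct_peaks": ppg.distinct_peaks,
                    "genes_per_category": genes_per_category(table, gl),
                }
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / "per_gene_counts.tsv", sep="\t", index=False)
            pd.concat(cats.values(), ignore_index=True).to_csv(
                out / "peak_categories.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("annotate", exc) from exc
    else:
        summary["stages"]["annotate"] = "skipped (needs peaks + genes)"

    # -- enrich ------------------------------------------------------------
    if peaks is not None and gene_lists is not None and genome is not None:
        try:
            report = proximity_enrichment(
                peaks,
                gene_lists,
                genome,
                window=params["window"],
                merge_windows=params["merge_windows"],
                peak_point=params["peak_point"],
            )
            io.write_json(report.to_dict(), out / "enrichment.json")
            summary["stages"]["enrich"] = report.to_dict()
        except Exception as exc:  # noqa: BLE001
            raise StageError("enrich", exc) from exc
    else:
        summary["stages"]["enrich"] = "skipped (needs peaks + genes + chrom_sizes)"

    # -- histogram ---------------------------------------------------------
    if peaks is not None and gene_lists is not None:
        try:
            import pandas as pd

            frames = []
            for gl in gene_lists:
                hist = tss_histogram(
                    peaks, gl, distance_range=params["window"], bin_width=params["bin_width"]
                )
                frame = hist.to_frame()
                frame.insert(0, "list", gl.label)
                frames.append(frame)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "tss_histogram.tsv", sep="\t", index=False
            )
            summary["stages"]["histogram"] = {
                gl.label: "ok" for gl in gene_lists
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("histogram", exc) from exc

    # -- overlap -----------------------------------------------------------
    if peaks is not None and "peaks_b" in inputs:
        try:
            b = io.read_bed(inputs["peaks_b"], genome=genome, label="factor_b")
            c = (
                io.read_bed(inputs["peaks_c"], genome=genome, label="factor_c")
                if "peaks_c" in inputs
                else None
            )
            summ = overlap_summary(peaks, b, c)
            io.write_json(summ.to_dict(), out / "overlap.json")
            summary["stages"]["overlap"] = summ.to_dict()
        except Exception as exc:  # noqa: BLE001
            raise StageError("overlap", exc) from exc
    else:
        summary["stages"]["overlap"] = "skipped (needs peaks_b)"

    # -- motif stages ------------------------------------------------------
    if "sequences" in inputs:
        try:
            seqs = io.read_fasta(inputs["sequences"])
            motif = params["motif"]
            import pandas as pd

            hits = [
                vars(h) for sid, s in seqs for h in scan(s, motif, seq_id=sid)
            ]
            pd.DataFrame(hits, columns=["seq_id", "offset", "strand", "matched"]).to_csv(
                out / "motif_hits.tsv", sep="\t", index=False
            )
            cer = central_enrichment(seqs, motif, central_width=params["central_width"])
            io.write_json(vars(cer), out / "central_enrichment.json")
            spr = spaced_pair(seqs, motif, motif, max_gap=params["max_gap"])
            io.write_json(
                {
                    "counts": spr.counts.tolist(),
                    "best_gap": spr.best_gap,
                    "n_pairs": spr.n_pairs,
                    "p_value": spr.p_value,
                },
                out / "spaced_pair.json",
            )
            summary["stages"]["motif"] = {
                "n_hits": len(hits),
                "central_enrichment_p": cer.p_value,
                "spaced_pair_best_gap": spr.best_gap,
                "spaced_pair_p": spr.p_value,
            }
            if "negative_sequences" in inputs:
                negs = io.read_fasta(inputs["negative_sequences"])
                found = discover(
                    seqs, negs, k_range=range(params["k_min"], params["k_max"] + 1)
                )
                io.write_json([vars(d) for d in found], out / "discovered_motifs.json")
                summary["stages"]["discover"] = [vars(d) for d in found]
            else:
                summary["stages"]["discover"] = "skipped (needs negative_sequences)"
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("motif", exc) from exc
    else:
        summary["stages"]["motif"] = "skipped (no sequences)"

    summary["wall_clock_s"] = round(time.time() - t0, 3)
    io.write_json(summary, out / "summary.json")
    return summary
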