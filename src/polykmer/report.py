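"""Serialization and plotting of size reports."""

from __future__ import annotations

import json
import os

import numpy as np

from .histogram import KmerHistogram
from .model import FitComponent, SizeReport

__all__ = ["write_report", "report_to_dict", "report_from_dict", "render_plot"]

_MB = 1e6  # base-10 megabases


def report_to_dict(report: SizeReport) -> dict:
    """JSON-ready dict carrying every numeric field of the report."""
    return {
        "c_het": report.c_het,
        "ploidy": report.ploidy,
        "error_cutoff": report.error_cutoff,
        "region_sizes": list(report.region_sizes),
        "repeat_size": report.repeat_size,
        "genome_size": report.genome_size,
        "genome_size_mb": report.genome_size / _MB,
        "full_size": report.full_size,
        "full_size_mb": report.full_size / _MB,
        "observed_instances": report.observed_instances,
        "residual_instances": report.residual_instances,
        "floored_loss": report.floored_loss,
        "warnings": list(report.warnings),
        "components": [
            {
                "index": c.index,
                "mean": c.mean,
                "sd": c.sd,
                "amplitude": c.amplitude,
                "converged": c.converged,
                "window": list(c.window),
                "fitted_curve": c.fitted_curve.tolist(),
            }
            for c in report.components
        ],
    }


def report_from_dict(data: dict) -> SizeReport:
    """Inverse of :func:`report_to_dict` (exact numeric round-trip)."""
    comps = tuple(
        FitComponent(
            index=c["index"],
            mean=c["mean"],
            sd=c["sd"],
            amplitude=c["amplitude"],
            fitted_curve=np.asarray(c["fitted_curve"], dtype=np.float64),
            converged=c["converged"],
            window=tuple(c["window"]),
        )
        for c in data["components"]
    )
    return SizeReport(
        c_het=data["c_het"],
        ploidy=data["ploidy"],
        region_sizes=tuple(data["region_sizes"]),
        repeat_size=data["repeat_size"],
        genome_size=data["genome_size"],
        full_size=data["full_size"],
        components=comps,
        error_cutoff=data["error_cutoff"],
        residual_instances=data["residual_instances"],
        observed_instances=data["observed_instances"],
        floored_loss=data["floored_loss"],
        warnings=tuple(data["warnings"]),
    )


def write_report(
    report: SizeReport,
    formats: set[str] | list[str] = ("tsv", "json"),
    output_dir: str | os.PathLike = ".",
) -> dict[str, str]:
    """Write the report in the requested formats; returns {format: path}.

    The TSV carries the scalars as ``#``-prefixed header lines, then one row
    per sharing class (index, fitted mean, sd, amplitude, size in bases and
    Mb) plus a repeat row.  The JSON round-trips to the in-memory report
    exactly via :func:`report_from_dict`.
    """
    os.makedirs(output_dir, exist_ok=True)
    paths: dict[str, str] = {}
    formats = set(formats)
    unknown = formats - {"tsv", "json"}
    if unknown:
        raise ValueError(f"unknown report formats: {sorted(unknown)}")
    if "tsv" in formats:
        path = os.path.join(output_dir, "report.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# c_het\t{report.c_het!r}\n")
            fh.write(f"# ploidy\t{report.ploidy}\n")
            fh.write(f"# error_cutoff\t{report.error_cutoff}\n")
            fh.write(f"# genome_size_bases\t{report.genome_size!r}\n")
            fh.write(f"# genome_size_mb\t{report.genome_size / _MB:.6f}\n")
            fh.write(f"# full_size_bases\t{report.full_size!r}\n")
            fh.write(f"# full_size_mb\t{report.full_size / _MB:.6f}\n")
            fh.write("class\tmean\tsd\tamplitude\tsize_bases\tsize_mb\n")
            for comp, g in zip(report.components, report.region_sizes):
                fh.write(
                    f"{comp.index}\t{comp.mean!r}\t{comp.sd!r}\t{comp.amplitude!r}"
                    f"\t{g!r}\t{g / _MB:.6f}\n"
                )
            fh.write(f"repeat\t\t\t\t{report.repeat_size!r}\t{report.repeat_size / _MB:.6f}\n")
        paths["tsv"] = path
    if "json" in formats:
        path = os.path.join(output_dir, "report.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report_to_dict(report), fh, indent=1)
            fh.write("\n")
        paths["json"] = path
    return paths


def render_plot(
    hist: KmerHistogram,
    report: SizeReport,
    xlim: tuple[float, float] | None = None,
    ylim: tuple[float, float] | None = None,
    path: str | os.PathLike = "spectrum.png",
) -> str:
    """Observed spectrum, fitted components, their sum, and C_het multiples.

    Axis limits are honored when given, else the x range auto-scales to cover
    the error cutoff through ``(p + 1) * C_het``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    dense = hist.dense()
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(dense.coverages, dense.frequencies, color="0.3", lw=1.2, label="observed")
    total = np.zeros(dense.coverages.size)
    for comp, g in zip(report.components, report.region_sizes):
        curve = comp.fitted_curve
        if curve.size != total.size:  # report fitted on a clipped grid
            padded = np.zeros_like(total)
            padded[: curve.size] = curve[: total.size]
            curve = padded
        total += curve
        ax.plot(
            dense.coverages,
            curve,
            lw=1.0,
            label=f"{comp.index} homolog(s): {g / _MB:.2f} Mb",
        )
    ax.plot(dense.coverages, total, "--", color="crimson", lw=1.2, label="fitted sum")
    for i in range(1, report.ploidy + 1):
        ax.axvline(i * report.c_het, color="0.8", lw=0.6, zorder=0)
    ax.set_xlabel("k-mer coverage")
    ax.set_ylabel("distinct k-mers")
    ax.set_title(
        f"G = {report.genome_size / _MB:.2f} Mb (haploid avg), "
        f"G*p = {report.full_size / _MB:.2f} Mb, C_het = {report.c_het:.1f}"
    )
    if xlim is not None:
        ax.set_xlim(*xlim)
    else:
        ax.set_xlim(0, min(dense.max_coverage, (report.ploidy + 1) * report.c_het))
    if ylim is not None:
        ax.set_ylim(*ylim)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return str(path)
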