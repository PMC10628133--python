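"""End-to-end orchestration: correct -> infer -> sv -> afs.

A :class:`RunConfig` collects all inputs, thresholds and seeds; it
round-trips losslessly through YAML.  :func:`run_pipeline` executes the
stages in order and writes every artifact with a manifest carrying the
config, seeds and package version, so a run is reproducible byte for byte.
:func:`simulate_scenario` emits the named synthetic fixture bundles (maps,
covariates, allele tables and machine-readable truth) used by the test
suite and the examples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .allele import (
    classify_window_state,
    compute_window_spectra,
    read_allele_table,
    select_informative_snps,
)
from .contacts import (
    DiagonalTrack,
    extract_diagonal,
    read_bedgraph,
    read_contact_map,
    write_bedgraph,
    write_contact_map,
)
from .correction import apply_correction, fit_correction, fit_correction_internal
from .genome import Karyotype, make_bins, read_chrom_sizes
from .purity import MixtureDecomposition, decompose, estimate_mode_scale
from .simulate import (
    CovariateTrack,
    SimulationParams,
    mix_maps,
    render_expected_map,
    sample_reads,
    simulate_allele_counts,
    simulate_covariates,
)
from .sv import calls_to_bedpe, detect_type1, detect_type2
from . import scenarios as _scen

__all__ = ["RunConfig", "run_pipeline", "simulate_scenario", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure with a defined CLI exit code."""

    def __init__(self, message: str, exit_code: int = 3):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class RunConfig:
    """All inputs and knobs of one pipeline run."""

    chrom_sizes: str = ""
    bin_size: int = 50_000
    contact_map: str = ""
    reference_map: str | None = None
    gc: str = ""
    mappability: str = ""
    cut_sites: str = ""
    compartment: str = ""          # eigenvector bedGraph; sign -> A/B
    allele_table: str | None = None
    mode_copy_number: int = 2
    max_populations: int = 3
    fdr: float = 0.1
    seed: int = 17
    out_dir: str = "hicdeconv_run"
    verbosity: int = 1

    def validate(self) -> None:
        if not self.contact_map:
            raise PipelineError("config is missing the contact map path", 2)
        if not self.chrom_sizes:
            raise PipelineError("config is missing the chrom sizes path", 2)
        for name in ("gc", "mappability", "cut_sites", "compartment"):
            if not getattr(self, name) and not self.reference_map:
                raise PipelineError(
                    f"missing covariate track {name!r}; supply covariate "
                    "bedGraphs (with or without a reference map) or enable "
                    "internal diploid-bin fitting by providing covariates",
                    2,
                )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys {sorted(unknown)}", 2)
        return cls(**data)


def _log(cfg: RunConfig, msg: str) -> None:
    if cfg.verbosity > 0:
        print(f"[hicdeconv] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig, stages=("correct", "infer", "sv", "afs")) -> dict:
    """Execute the pipeline; returns a result bundle and writes artifacts."""
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    bins = make_bins(read_chrom_sizes(config.chrom_sizes), config.bin_size)
    cmap = read_contact_map(config.contact_map, bins)
    cov = CovariateTrack(
        gc=read_bedgraph(config.gc, bins),
        mappability=read_bedgraph(config.mappability, bins),
        cut_sites=read_bedgraph(config.cut_sites, bins),
        compartment=np.where(read_bedgraph(config.compartment, bins) >= 0, 1, -1)
        .astype(np.int8),
    )
    results: dict = {}
    corrected: DiagonalTrack | None = None
    deco: MixtureDecomposition | None = None

    if "correct" in stages:
        _log(config, "stage correct")
        diag = extract_diagonal(cmap)
        if config.reference_map:
            ref = read_contact_map(config.reference_map, bins)
            model = fit_correction(extract_diagonal(ref), cov)
        else:
            model = fit_correction_internal(diag, cov)
        corrected = apply_correction(diag, cov, model)
        (out / "correction_model.json").write_text(model.to_json())
        write_bedgraph(corrected, out / "corrected_diagonal.bedGraph")
        results["correction_model"] = model
        results["corrected"] = corrected

    if "infer" in stages:
        if corrected is None:
            raise PipelineError("infer stage requires the correct stage")
        _log(config, "stage infer")
        deco = decompose(
            corrected,
            mode_copy_number=config.mode_copy_number,
            max_populations=config.max_populations,
            seed=int(rng.integers(2**31)),
            compute_ci=True,
        )
        results["decomposition"] = deco
        _write_decomposition(deco, bins, out)

    if "sv" in stages:
        if deco is None:
            raise PipelineError("sv stage requires the infer stage")
        _log(config, "stage sv")
        seed_sv = int(rng.integers(2**31))
        calls = detect_type1(cmap, deco, fdr=config.fdr, seed=seed_sv)
        calls += detect_type2(cmap, fdr=config.fdr, seed=seed_sv + 1)
        results["sv_calls"] = calls
        (out / "sv_calls.bedpe").write_text(calls_to_bedpe(calls, bins))
        _write_sv_table(calls, bins, out / "sv_calls.tsv")

    if "afs" in stages and config.allele_table:
        _log(config, "stage afs")
        table = select_informative_snps(read_allele_table(config.allele_table))
        spectra = compute_window_spectra(table, bins)
        results["spectra"] = spectra
        f_total = sum(deco.fractions) if deco and deco.fractions else 0.0
        rows = []
        for sp in spectra:
            n = 2
            if deco is not None and deco.populations:
                cn = deco.populations[0].profile.cn_track(bins.n_bins)
                b = bins.locus_to_bin(sp.chrom, min(sp.start, bins.chrom_sizes[sp.chrom] - 1))
                n = int(cn[b])
            f_use = deco.fractions[0] if deco and deco.fractions else 0.0
            state, cfg_ab, dist = classify_window_state(sp, f_use, n)
            rows.append(
                (sp.chrom, sp.start, sp.end, state,
                 "NA" if cfg_ab is None else f"{cfg_ab[0]}:{cfg_ab[1]}",
                 f"{dist:.4f}" if np.isfinite(dist) else "inf",
                 ",".join(f"{p:.3f}" for p in sp.peaks))
            )
        with open(out / "window_states.tsv", "w") as fh:
            fh.write("#chrom\tstart\tend\tstate\thaplotypes\tdistance\tpeaks\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
        results["window_states"] = rows

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_sha256": hashlib.sha256(
            config.to_yaml().encode()
        ).hexdigest(),
        "stages": list(stages),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def _write_decomposition(deco: MixtureDecomposition, bins, out: Path) -> None:
    with open(out / "segments.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tpopulation\tcn\tconfidence\n")
        for k, pop in enumerate(deco.populations):
            conf = {cp.bin: cp.confidence for cp in pop.profile.change_points}
            for seg in pop.profile.segments:
                _, s, _ = bins.bin_to_interval(seg.start_bin)
                _, _, e = bins.bin_to_interval(seg.end_bin - 1)
                e = min(e, bins.chrom_sizes[seg.chrom])
                c = conf.get(seg.start_bin, np.nan)
                fh.write(
                    f"{seg.chrom}\t{s}\t{e}\t{pop.label}\t{seg.cn}\t"
                    f"{'' if np.isnan(c) else round(c, 4)}\n"
                )
    report = {
        "scale_C": deco.scale,
        "discrepancy": deco.discrepancy,
        "normal_fraction": deco.normal_fraction,
        "populations": [
            {
                "label": p.label,
                "fraction": p.fraction,
                "ci95": list(deco.f_confidence_intervals[k])
                if k < len(deco.f_confidence_intervals)
                else None,
                "aberrant_fraction": p.profile.aberrant_fraction(bins.n_bins),
            }
            for k, p in enumerate(deco.populations)
        ],
    }
    (out / "purity_report.json").write_text(json.dumps(report, indent=2))
    if deco.populations:
        np.savetxt(
            out / "discrepancy_curve.tsv",
            np.column_stack(
                [deco.populations[0].f_grid, deco.populations[0].d_curve]
            ),
            header="f\tD", delimiter="\t", comments="#",
        )


def _write_sv_table(calls, bins, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom_a\tpos_a\tchrom_b\tpos_b\tsv_type\tpattern\tp\tq\t"
            "focal\tpopulation\tcn\tflags\n"
        )
        for c in calls:
            _, pa, _ = bins.bin_to_interval(c.bin_a)
            _, pb, _ = bins.bin_to_interval(c.bin_b)
            flags = ",".join(
                f for f, on in (("low_conf", c.low_confidence), ("tie", c.tie_flag))
                if on
            )
            fh.write(
                f"{c.chrom_a}\t{pa}\t{c.chrom_b}\t{pb}\t{c.sv_type}\t"
                f"{c.pattern_class}\t{c.p_value:.3e}\t{c.q_value:.3e}\t"
                f"{c.focal_intensity:.3f}\t{c.assigned_population or ''}\t"
                f"{'' if c.assigned_copy_number is None else c.assigned_copy_number}"
                f"\t{flags}\n"
            )


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------

SCENARIOS = ("insilico_purity", "invitro_purity", "null", "fusion")


def simulate_scenario(
    name: str,
    out_dir,
    seed: int = 17,
    scale: float = 1.0,
    read_depth: float = 1e7,
) -> dict:
    """Write a named fixture bundle (maps, covariates, truth) to out_dir.

    ``insilico_purity``: aneuploid/diploid read mixtures at cancer weights
    0.76, 0.48, 0.28 with Poisson noise.  ``invitro_purity``: the same
    genomes at 0.50, 0.33, 0.20 with over-dispersed counts.  ``null``: a
    pure diploid map.  ``fusion``: one non-reciprocal and one reciprocal
    translocation at cancer fraction 0.5.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes = _scen.toy_chrom_sizes(scale)
    bins = make_bins(sizes, _scen.BIN_SIZE)
    with open(out / "toy.chrom.sizes", "w") as fh:
        for c, s in sizes.items():
            fh.write(f"{c}\t{s}\n")
    cov = simulate_covariates(bins, seed=seed)
    params = SimulationParams()
    _write_covariates(cov, bins, out)

    normal = _scen.diploid_karyotype(sizes)
    truth: dict = {"scenario": name, "seed": seed, "bin_size": _scen.BIN_SIZE}
    rng = np.random.default_rng(seed)

    def render(karyotype):
        return render_expected_map([(karyotype, 1.0)], bins, cov, params)

    diploid_expected = render(normal)
    ref = sample_reads(diploid_expected, read_depth, int(rng.integers(2**31)))
    write_contact_map(ref, out / "reference.tsv")

    if name in ("insilico_purity", "invitro_purity"):
        cancer = _scen.aneuploid_karyotype(sizes)
        cancer.write(out / "cancer.karyotype.txt")
        cancer_expected = render(cancer)
        dispersion = 0.1 if name == "invitro_purity" else None
        weights = (0.76, 0.48, 0.28) if name == "insilico_purity" else (0.50, 0.33, 0.20)
        truth["mixtures"] = []
        cancer_reads = sample_reads(
            cancer_expected, read_depth, int(rng.integers(2**31)), dispersion
        )
        normal_reads = sample_reads(
            diploid_expected, read_depth, int(rng.integers(2**31)), dispersion
        )
        for w in weights:
            mixed = mix_maps([cancer_reads, normal_reads], [w, 1 - w])
            path = out / f"mixture_{int(round(100 * w))}.tsv"
            write_contact_map(mixed, path)
            truth["mixtures"].append({"path": path.name, "cancer_fraction": w})
        truth["cn_track"] = cancer.cn_track(bins).tolist()
    elif name == "null":
        sample = sample_reads(
            diploid_expected, read_depth, int(rng.integers(2**31))
        )
        write_contact_map(sample, out / "sample.tsv")
        truth["cancer_fraction"] = 0.0
    elif name == "fusion":
        fused = _scen.fusion_karyotype(sizes)
        recip = _scen.reciprocal_karyotype(sizes)
        cancer_expected = render_expected_map(
            [(fused, 0.5), (recip, 0.5)], bins, cov, params
        )
        mixture = render_expected_map(
            [(fused, 0.25), (recip, 0.25), (normal, 0.5)], bins, cov, params
        )
        sample = sample_reads(mixture, read_depth, int(rng.integers(2**31)))
        write_contact_map(sample, out / "sample.tsv")
        truth["fusions"] = [
            {"chrom_a": "chr1", "pos_a": int(sizes["chr1"] * 0.6),
             "chrom_b": "chr2", "pos_b": int(sizes["chr2"] * 0.4),
             "type": "type1"},
            {"chrom_a": "chr3", "pos_a": int(sizes["chr3"] * 0.6),
             "chrom_b": "chr4", "pos_b": int(sizes["chr4"] * 0.4),
             "type": "type2"},
        ]
        truth["cancer_fraction"] = 0.5
    else:
        raise PipelineError(f"unknown scenario {name!r}", 2)

    # allele counts for mixture-style scenarios
    if name in ("insilico_purity", "invitro_purity"):
        cancer = _scen.aneuploid_karyotype(sizes)
        table = simulate_allele_counts(
            [(cancer, 0.56), (normal, 0.44)], bins, n_snps=int(2000 * scale) + 200,
            depth=40, seed=int(rng.integers(2**31)),
        )
        table.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
        truth["allele_cancer_fraction"] = 0.56

    (out / "truth.json").write_text(json.dumps(truth))
    return truth


def _write_covariates(cov: CovariateTrack, bins, out: Path) -> None:
    for nm, arr in (
        ("gc", cov.gc),
        ("mappability", cov.mappability),
        ("cut_sites", cov.cut_sites),
        ("compartment", cov.compartment.astype(float)),
    ):
        track = DiagonalTrack(bins, np.asarray(arr, dtype=float),
                              np.ones(bins.n_bins, dtype=bool))
        write_bedgraph(track, out / f"{nm}.bedGraph")
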