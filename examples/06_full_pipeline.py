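"""End-to-end: simulate a fixture bundle, then run the full pipeline.

Writes maps/covariates/truth to disk, runs correct -> infer -> sv -> afs
from files (as the CLI does), and prints the purity report.
"""
import json, tempfile
from pathlib import Path
from hicdeconv.pipeline import RunConfig, run_pipeline, simulate_scenario

work = Path(tempfile.mkdtemp(prefix="hicdeconv_demo_"))
truth = simulate_scenario("insilico_purity", work / "fixture",
                          seed=17, scale=0.2, read_depth=2e6)
fx = work / "fixture"
cfg = RunConfig(
    chrom_sizes=str(fx / "toy.chrom.sizes"),
    contact_map=str(fx / "mixture_48.tsv"),
    reference_map=str(fx / "reference.tsv"),
    gc=str(fx / "gc.bedGraph"), mappability=str(fx / "mappability.bedGraph"),
    cut_sites=str(fx / "cut_sites.bedGraph"),
    compartment=str(fx / "compartment.bedGraph"),
    allele_table=str(fx / "allele_counts.tsv"),
    seed=17, out_dir=str(work / "run"))
run_pipeline(cfg)
report = json.loads((work / "run" / "purity_report.json").read_text())
print(json.dumps(report, indent=2))
print(f"truth: cancer read fraction 0.48; outputs under {work}/run")
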