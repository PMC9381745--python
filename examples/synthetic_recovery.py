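"""Write a noiseless synthetic bundle, run the full pipeline, compare to truth.

Demonstrates the end-to-end guarantee: on data generated exactly from known
parameters, every stage of the analysis recovers those parameters.
"""

import json
import tempfile
from pathlib import Path

from atpskit import RunConfig, run_full_analysis
from atpskit.synthetic import GeneratorConfig, write_dataset

config = GeneratorConfig(
    seed=5, binodal_noise_sd=0.0, partition_noise_sd=0.0, refractometry_noise_sd=0.0
)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_dataset(config, Path(tmp) / "data")
    truth = json.loads(paths["truth"].read_text())
    report = run_full_analysis(RunConfig(
        binodal_csv=paths["binodal"],
        tielines_csv=paths["tielines"],
        partition_csv=paths["partition"],
    ))

mk = report["binodal"]["merchuk"]
print("Merchuk binodal:  truth vs recovered")
for key in ("a", "b", "c"):
    print(f"  {key}: {truth['binodal'][key]:12.6g}   {mk[key]:12.6g}")
for drug, params in truth["partition"].items():
    got = report["partitioning"]["correlations"][drug]["diamond_hsu"]
    print(f"Diamond-Hsu ({drug}):")
    print(f"  A: {params['A']:12.6g}   {got['A']:12.6g}")
    print(f"  B: {params['B']:12.6g}   {got['B']:12.6g}")
print()
print("With all noise channels off the recovered parameters equal the")
print("generating truth to numerical precision — the pipeline is exact on its")
print("own model class.")
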