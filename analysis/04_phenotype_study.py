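"""Run the microscopy crop / rotation / dual-objective study with the ablation.

On centered-cell images, trains per seed: the random-crop composition, the
strong-rotation composition, the center-focused composition, and the
dual-composition weighted objective; computes condition AMI (k-means, k = 2)
and phenotype AMI (k = 4) on the frozen embeddings. The ablation mode then
adds the center-focused set's transformations one at a time while holding the
crop set fixed, recording AMI per step.

Writes results/phenotype/{table.csv,summary.csv,ablation.csv,manifest.json}.
"""

import os

from augbias import pipeline

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "phenotype")


def main():
    cfg = pipeline.default_phenotype_config(out_dir=OUT)
    artifacts = pipeline.run_phenotype_study(cfg, ablation=True)
    pipeline.write_report(artifacts, cfg, OUT, overwrite=True)
    summary = artifacts["summary"]
    print(summary.round(3).to_string())
    med = summary["ami_condition"]
    print(f"\nReplacing random crops with strong rotations raises condition AMI "
          f"from {med['crop']:.3f} to {med['rotation']:.3f} (median over seeds); "
          f"the center-focused set reaches {med['center']:.3f} and the dual "
          f"objective {med['dual']:.3f}.")
    ab = artifacts["ablation"].groupby("step")["ami_condition"].agg(["mean", "std"])
    print("\nProgressive integration of the center-focused set:")
    print(ab.round(3).to_string())


if __name__ == "__main__":
    main()
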