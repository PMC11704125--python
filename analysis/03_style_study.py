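"""Run the two-transformation-set glyph study and report what each set encodes.

Set 1 (padding, inversion, slight rotation, mild crops) preserves glyph
identity across views; set 2 (vertical flips, full-circle rotation, crops,
erasing) destroys it while leaving stroke style intact. For each set and five
seeds this trains an encoder, clusters its embeddings (k = number of glyph
classes), and reports AMI against glyph labels, AMI against style labels,
probe accuracy, silhouette and the perceptual dissimilarity of view pairs.

Writes results/style/{table.csv,summary.csv,manifest.json}.
"""

import os

from augbias import pipeline

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "style")


def main():
    cfg = pipeline.default_style_config(out_dir=OUT)
    artifacts = pipeline.run_style_study(cfg)
    pipeline.write_report(artifacts, cfg, OUT, overwrite=True)
    summary = artifacts["summary"]
    print(summary.round(3).to_string())
    s1, s2 = summary.loc["set1"], summary.loc["set2"]
    print(f"\nSet 1 clusters align with glyph identity (AMI {s1.ami_glyph:.2f} "
          f"vs style {s1.ami_style:.2f}); set 2 with stroke style "
          f"(AMI {s2.ami_style:.2f} vs glyph {s2.ami_glyph:.2f}).")
    print(f"Set 2 degrades glyph probing ({s2.top1_glyph:.2f} vs {s1.top1_glyph:.2f}) "
          f"and distorts views more (dissimilarity {s2.perceptual:.2f} vs {s1.perceptual:.2f}).")


if __name__ == "__main__":
    main()
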