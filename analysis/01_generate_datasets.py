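"""Generate the three synthetic datasets the studies run on and summarize them.

Writes PNG directories with labels.csv sidecars under results/datasets/ plus a
summary table of per-dataset composition. The cell images emulate centered
single-cell microscopy crops with an untreated and a treated condition (three
morphological sub-phenotypes plus a lookalike subpopulation); the glyph images
carry two independent factors (stroke orientation class, stroke-thickness
style); the property classes have controlled texture/spectral/latent structure
for the class-property metrics.
"""

import os

import numpy as np
import pandas as pd

from augbias.pipeline import default_phenotype_config, default_style_config, make_dataset
from augbias.synthgen import gen_property_classes

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "datasets")


def main():
    os.makedirs(OUT, exist_ok=True)
    rows = []

    cells = make_dataset(default_phenotype_config().dataset)
    cells.save_png_dir(os.path.join(OUT, "cells"))
    rows.append({
        "dataset": "cells",
        "n": len(cells),
        "classes": int(cells.labels.max()) + 1,
        "note": "treated lookalike fraction %.2f" % (
            (cells.aux_labels[cells.labels == 1] == 0).mean()),
    })

    glyphs = make_dataset(default_style_config().dataset)
    glyphs.save_png_dir(os.path.join(OUT, "glyphs"))
    rows.append({
        "dataset": "glyphs",
        "n": len(glyphs),
        "classes": int(glyphs.labels.max()) + 1,
        "note": "styles balanced %.2f" % (glyphs.aux_labels == 0).mean(),
    })

    props = gen_property_classes(6, 60, seed=11)
    props.save_png_dir(os.path.join(OUT, "properties"))
    rows.append({"dataset": "properties", "n": len(props),
                 "classes": int(props.labels.max()) + 1,
                 "note": "kinds: " + str(props.meta["kinds"])})

    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(OUT, "summary.csv"), index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
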