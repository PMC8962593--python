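"""Consensus pathway selection with an ensemble of tiny neural networks.

200 independently initialized two-hidden-neuron networks are trained by
Levenberg-Marquardt on the screening data; each predicts all genotypes and
nominates its top 10.  Genotypes nominated more often than half as often as
the most-nominated one form the consensus build list.
"""

import numpy as np

from pathwayopt import (
    build_design_matrix,
    default_hill,
    default_landscape,
    default_library,
    filter_dataset,
    scale_from_library,
    select_range_covering_subset,
    simulate_screen,
)
from pathwayopt.ann import AnnArchitecture, encode_ann_inputs, ensemble_select
from pathwayopt.io import colonies_to_records
from pathwayopt.space import LibrarySpec, enumerate_space

library = default_library()
scale = scale_from_library(library)
screen = simulate_screen(library, default_landscape(), default_hill(), 190, seed=1)
records = colonies_to_records(select_range_covering_subset(screen, 35))
filtered, _ = filter_dataset(records)
design = build_design_matrix(filtered, scale, library)
cds_levels = design.attrs["cds_levels"]
titer = np.array([r.titer for r in filtered])

reduced = LibrarySpec(operons=tuple(
    type(o)(step=o.step, promoters=o.promoters,
            cds_variants=tuple(c for c in o.cds_variants
                               if c.id in cds_levels[o.step]))
    for o in library.operons
))
space = enumerate_space(reduced)
train_X = encode_ann_inputs([r.genotype for r in filtered], scale, library, cds_levels)
space_X = encode_ann_inputs(space, scale, library, cds_levels)
print(f"{train_X.shape[1]} input neurons; scoring {len(space)} genotypes")

arch = AnnArchitecture(n_inputs=train_X.shape[1], n_hidden=2)
result = ensemble_select(
    train_X.to_numpy(), titer, space_X.to_numpy(), arch,
    n_iterations=200, k=10, seed=0, space=space,
)
print(f"f_max = {result.f_max} of {result.n_iterations} nominations; "
      f"threshold {result.threshold:.0f}")
print(result.to_frame().to_string(index=False))
# f is how many networks nominated the genotype; a consensus spread over
# few genotypes means the ensemble agrees on where the optimum lies.
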