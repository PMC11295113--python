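"""Parse code hierarchies and build an ancestor-closed one-hot matrix.

Shows the two hierarchy flavours (rule-driven ATC prefixes, table-driven
ICD chapters/blocks) and how a record carrying a deep code also carries
every ancestor as its own binary column.
"""

import pandas as pd

from codesel import (
    encode_one_hot,
    load_example_hierarchy,
    parse_atc_ancestors,
)

# ATC codes are fixed-width prefixes: ancestors come from truncation.
print("ancestors of C07AB02 (metoprolol):", parse_atc_ancestors("C07AB02"))

# ICD block ranges cannot be derived from the code string, so the ICD
# hierarchy is a table; a miniature one ships with the package.
icd = load_example_hierarchy("icd")
print("ancestors of I251:", icd.ancestors("I251"))
print("depth of I251:", icd.depth("I251"))

# One aggregated record carrying a single deep code expands into the
# code plus all its ancestors (ancestor closure).
agg = pd.DataFrame({"patient_id": ["p1"], "window_index": [0],
                    "codes": [frozenset({"I251"})]})
matrix = encode_one_hot(agg, icd)
active = [c for c, v in zip(matrix.feature_codes, matrix.values[0]) if v]
print("columns set by {I251}:", active)
# Four columns fire for one observed code: the expansion code, its
# category, its block and its chapter - that redundancy is exactly what
# depth-aware feature selection has to contend with.
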