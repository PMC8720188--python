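"""Region lookup for the 90-region neonatal AAL parcellation.

The neonatal AAL atlas keeps the 90 cerebral regions of the adult AAL
parcellation (45 homologous left/right pairs; cerebellum and vermis excluded),
with labels 1..90 ordered as left/right pairs. Users working with a different
parcellation can pass their own label table wherever ``region_names`` is
accepted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# 45 homologous structures, AAL ordering. Each expands to a Left/Right pair.
_STRUCTURES = [
    "precentral gyrus",
    "superior frontal gyrus, dorsolateral",
    "superior frontal gyrus, orbital part",
    "middle frontal gyrus",
    "middle frontal gyrus, orbital part",
    "inferior frontal gyrus, opercular part",
    "inferior frontal gyrus, triangular part",
    "inferior frontal gyrus, orbital part",
    "rolandic operculum",
    "supplementary motor area",
    "olfactory cortex",
    "superior frontal gyrus, medial",
    "superior frontal gyrus, medial orbital",
    "gyrus rectus",
    "insula",
    "anterior cingulate and paracingulate gyri",
    "median cingulate and paracingulate gyri",
    "posterior cingulate gyrus",
    "hippocampus",
    "parahippocampal gyrus",
    "amygdala",
    "calcarine fissure and surrounding cortex",
    "cuneus",
    "lingual gyrus",
    "superior occipital gyrus",
    "middle occipital gyrus",
    "inferior occipital gyrus",
    "fusiform gyrus",
    "postcentral gyrus",
    "superior parietal gyrus",
    "inferior parietal gyrus",
    "supramarginal gyrus",
    "angular gyrus",
    "precuneus",
    "paracentral lobule",
    "caudate nucleus",
    "lenticular nucleus, putamen",
    "lenticular nucleus, pallidum",
    "thalamus",
    "heschl gyrus",
    "superior temporal gyrus",
    "temporal pole: superior temporal gyrus",
    "middle temporal gyrus",
    "temporal pole: middle temporal gyrus",
    "inferior temporal gyrus",
]

N_REGIONS = 2 * len(_STRUCTURES)


def region_names() -> list[str]:
    """Return the 90 region names, label order (Left/Right interleaved)."""
    names = []
    for s in _STRUCTURES:
        names.append(f"Left {s}")
        names.append(f"Right {s}")
    return names


def region_table() -> pd.DataFrame:
    """Lookup table with columns ``label`` (1..90), ``name`` and ``hemisphere``."""
    names = region_names()
    return pd.DataFrame(
        {
            "label": np.arange(1, N_REGIONS + 1),
            "name": names,
            "hemisphere": ["L", "R"] * len(_STRUCTURES),
        }
    )
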