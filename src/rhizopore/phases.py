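"""Phase label codes shared across the pipeline.

The same uint8 coding is used for synthetic ground-truth volumes and for
segmentation outputs so label TIFFs from either source are interchangeable.
"""

PORE = 0
SOLID = 1
ROOT = 2
EXCLUDED = 3
REFERENCE = 4

PHASE_NAMES = {
    PORE: "pore",
    SOLID: "solid",
    ROOT: "root",
    EXCLUDED: "excluded",
    REFERENCE: "reference",
}
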