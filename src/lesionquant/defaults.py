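"""Package-wide default parameters.

Patch geometry defaults are chosen for the scale of the bundled synthetic
slides (lesion blobs tens to a couple of hundred pixels across): the
likelihood-map threshold pulls the recovered lesion boundary inward by a
distance proportional to the patch size, so the patch must be small relative
to a lesion diameter for unbiased area recovery.  See docs/methods.md.
"""

#: side of a (square) classification patch, px
PATCH_SIZE = 8
#: sliding-window stride, px
STRIDE = 4
#: minimum tissue fraction for a patch to be classified
MIN_TISSUE_FRAC = 0.5
#: likelihood-map threshold defining the lesion mask
THRESHOLD = 0.9

#: morphological cleanup after Otsu thresholding
OPENING_RADIUS_PX = 2
CLOSING_RADIUS_PX = 4
MIN_OBJECT_AREA_PX = 256
FILL_HOLES = True

#: connected-component filtering when counting lesions
COMPONENT_CONNECTIVITY = 8
MIN_COMPONENT_AREA_PX = 64

#: L2 regularization strength of the reference patch classifier
REG_STRENGTH = 1e-3
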