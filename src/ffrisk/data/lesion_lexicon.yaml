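# Lexicon for free-text coronary lesion descriptions.
#
# `phrases` are case-insensitive markers the translator searches for when a
# cell carries no percentage figure; `templates` are the phrasings the
# synthetic generator emits (qualitative templates must contain no digits so
# the numeric rules cannot fire on them). The source reports were hand
# translated, so these dialects are an emulation of plausible clinical
# phrasings, editable without code changes.
not_substantial:       # -> 10 % narrowing
  phrases:
    - "not substantial"
    - "no substantial"
    - "insignificant"
    - "non-significant"
    - "without significant"
  phrases_exclude: []
  templates:
    - "narrowing not substantial"
    - "no substantial stenosis of the vessel"
    - "insignificant narrowing of the lumen"
    - "diffuse non-significant stenosis"
very_minor:            # -> 5 % narrowing
  phrases:
    - "very minor"
    - "minimal narrowing"
    - "minimal stenosis"
    - "discrete parietal change"
  phrases_exclude: []
  templates:
    - "very minor narrowing"
    - "minimal narrowing of the vessel wall"
    - "minimal stenosis, discrete parietal changes"
orderly_lumen:         # -> no narrowing (0 %)
  phrases:
    - "orderly arterial lumen"
    - "orderly lumen"
    - "without stenosis"
    - "no narrowing"
    - "smooth contours, patent"
  phrases_exclude: []
  templates:
    - "orderly arterial lumen"
    - "orderly lumen, smooth contours, patent"
    - "vessel without stenosis"
percent_templates:     # explicit single percentage (translated verbatim)
  templates:
    - "stenosis of {p}%"
    - "narrowing of the proximal segment {p}%"
    - "{p}% diameter reduction"
    - "ostial stenosis {p}%"
range_templates:       # percentage range (translated as the range mean)
  templates:
    - "narrowing {a}-{b}%"
    - "stenosis in the range of {a} to {b}%"
    - "segmental stenosis {a}-{b}%"
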