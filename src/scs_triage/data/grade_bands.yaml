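# Published SUS interpretation scales, stored as data.
#
# letter_bands: the Sauro-Lewis curved grading scale — each entry is the
# inclusive upper edge of a letter band; a score falls in the first band
# whose upper edge is >= the score. 68 (the published all-studies average)
# sits in the C band, the scale's average band.
#
# adjective_anchors: Bangor's adjective-rating anchors (mean SUS per
# adjective); a score is assigned the nearest anchor's adjective.
average_threshold: 68.0
letter_bands:
  - {upper: 51.6, letter: F}
  - {upper: 62.6, letter: D}
  - {upper: 64.9, letter: C-}
  - {upper: 71.0, letter: C}
  - {upper: 72.5, letter: C+}
  - {upper: 74.0, letter: B-}
  - {upper: 77.1, letter: B}
  - {upper: 78.8, letter: B+}
  - {upper: 80.7, letter: A-}
  - {upper: 84.0, letter: A}
  - {upper: 100.0, letter: A+}
adjective_anchors:
  - {score: 12.5, adjective: worst imaginable}
  - {score: 20.3, adjective: awful}
  - {score: 35.7, adjective: poor}
  - {score: 50.9, adjective: ok}
  - {score: 71.4, adjective: good}
  - {score: 85.5, adjective: excellent}
  - {score: 100.0, adjective: best imaginable}
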