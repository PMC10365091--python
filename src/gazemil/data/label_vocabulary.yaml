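# Phrase vocabulary for the transcript labeler.
#
# Each entry maps one of the ten study labels to the lowercase phrases
# that assert it. Several source terms are grouped into one study label
# (e.g. "cardiomegaly" asserts Enlarged Cardiac Silhouette; "pulmonary
# edema" asserts both Edema and Opacity). `unmatch` phrases block a
# match they contain. This file is versioned configuration: edit or
# replace it (CLI `--vocabulary`) to change labeler behaviour.
labels:
  Abnormal Mediastinal Contour:
    match:
      - abnormal mediastinal contour
      - enlarged cardiomediastinum
      - widened mediastinum
      - mediastinal widening
    unmatch: []
  Atelectasis:
    match:
      - atelectasis
      - atelectatic
    unmatch: []
  Enlarged Cardiac Silhouette:
    match:
      - enlarged cardiac silhouette
      - cardiomegaly
      - heart is enlarged
      - cardiac enlargement
    unmatch: []
  Consolidation:
    match:
      - consolidation
      - consolidative
    unmatch: []
  Edema:
    match:
      - pulmonary edema
      - edema
    unmatch: []
  Fracture:
    match:
      - acute fracture
      - fracture
      - fractures
      - fractured
    unmatch: []
  Lung Lesion:
    match:
      - lung nodule or mass
      - lung lesion
      - nodule
      - nodules
      - mass
      - masses
    unmatch:
      - mass effect
  Opacity:
    match:
      - pulmonary edema
      - edema
      - lung nodule or mass
      - atelectasis
      - consolidation
      - groundglass opacity
      - ground glass opacity
      - interstitial lung disease
      - pneumonia
      - lung opacity
      - opacity
      - opacities
    unmatch: []
  Pleural Abnormality:
    match:
      - pleural abnormality
      - pleural other
      - pleural effusion
      - effusion
      - effusions
      - pleural thickening
    unmatch: []
  Pneumothorax:
    match:
      - pneumothorax
      - pneumothoraces
    unmatch: []
negation_cues:
  - "no"
  - "not"
  - without
  - negative for
  - clear of
  - free of
  - absence of
  - "no evidence of"
hedge_cues:
  - may represent
  - possible
  - possibly
  - cannot exclude
  - cannot be excluded
  - suggestive of
  - questionable
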