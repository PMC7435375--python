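# Default Mamdani FIS for drowsemeter.
#
# Membership breakpoints are tunable defaults, not measured constants:
# PERCLOS Low/Medium and Medium/High crossovers sit at 0.15 and 0.30
# (bracketing the 0.15-0.4 drowsiness thresholds reported across the
# PERCLOS literature), ECD crossovers at 1 s and 4 s, AOT crossovers at
# 2 s and 6 s.  Output levels are singletons on a normalized [0, 1]
# drowsiness scale; only their ordering matters for the label.
variables:
  perclos:
    universe: [0.0, 1.0]
    terms:
      Low:    {shape: trapezoidal, points: [0.0, 0.0, 0.10, 0.20]}
      Medium: {shape: trapezoidal, points: [0.10, 0.20, 0.25, 0.35]}
      High:   {shape: trapezoidal, points: [0.25, 0.35, 1.0, 1.0]}
  ecd:  # seconds
    universe: [0.0, 60.0]
    terms:
      Low:    {shape: trapezoidal, points: [0.0, 0.0, 0.5, 1.5]}
      Medium: {shape: trapezoidal, points: [0.5, 1.5, 3.0, 5.0]}
      High:   {shape: trapezoidal, points: [3.0, 5.0, 60.0, 60.0]}
  aot:  # seconds
    universe: [0.0, 60.0]
    terms:
      Low:    {shape: trapezoidal, points: [0.0, 0.0, 1.0, 3.0]}
      Medium: {shape: trapezoidal, points: [1.0, 3.0, 5.0, 7.0]}
      High:   {shape: trapezoidal, points: [5.0, 7.0, 60.0, 60.0]}

# Rule table: [perclos, ecd, aot, output].  Rows marked "anchored" encode
# the stated design constraints (all-Low stays Low; one eye indicator High
# with the rest Low gives Medium; two eye indicators Medium give Medium;
# AOT High plus another indicator Medium gives Medium; AOT High alone stays
# Low).  The remaining rows are the completion: the smallest output
# consistent with the anchors and with monotonicity; High requires both eye
# indicators High, or one High and the other Medium with AOT High.
rules:
  - [Low, Low, Low, Low]          # anchored
  - [Low, Low, Medium, Low]       # completion
  - [Low, Low, High, Low]         # anchored: AOT alone never raises the level
  - [Low, Medium, Low, Low]       # completion
  - [Low, Medium, Medium, Low]    # completion
  - [Low, Medium, High, Medium]   # anchored: AOT High + eye indicator Medium
  - [Low, High, Low, Medium]      # anchored: single eye indicator High
  - [Low, High, Medium, Medium]   # completion
  - [Low, High, High, Medium]     # completion
  - [Medium, Low, Low, Low]       # completion
  - [Medium, Low, Medium, Low]    # completion
  - [Medium, Low, High, Medium]   # anchored: AOT High + eye indicator Medium
  - [Medium, Medium, Low, Medium] # anchored: two eye indicators Medium
  - [Medium, Medium, Medium, Medium]  # completion
  - [Medium, Medium, High, Medium]    # completion
  - [Medium, High, Low, Medium]   # completion
  - [Medium, High, Medium, Medium]    # completion
  - [Medium, High, High, High]    # completion: High + Medium eyes, AOT High
  - [High, Low, Low, Medium]      # anchored: single eye indicator High
  - [High, Low, Medium, Medium]   # completion
  - [High, Low, High, Medium]     # completion
  - [High, Medium, Low, Medium]   # completion
  - [High, Medium, Medium, Medium]    # completion
  - [High, Medium, High, High]    # completion: High + Medium eyes, AOT High
  - [High, High, Low, High]       # completion: both eye indicators High
  - [High, High, Medium, High]    # completion
  - [High, High, High, High]      # completion

singletons: {Low: 0.0, Medium: 0.5, High: 1.0}
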