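# Advisory annotation-guideline criteria for screening vaccine tweets.
# Patterns are best-effort, case-insensitive substring/regex encodings of
# guidelines that were written for human annotators; they never override a
# manual label. polarity: misinformation | non-misinformation
criteria:
  - id: unsourced-treatment
    polarity: misinformation
    description: >
      Suggesting treatments or prophylaxis without any credible source of
      information (e.g. claiming a supplement beats vaccination, or that
      prior infection makes vaccination unnecessary).
    indicator_patterns:
      - "zinc .* more effective than .* vaccine"
      - "don'?t need (the |a )?vaccine because i already got covid"
      - "natural immunity is (all you need|better than any vaccine)"
  - id: unsourced-consequence-blame
    polarity: misinformation
    description: >
      Blaming vaccines for health consequences without a credible source.
    indicator_patterns:
      - "vaccine can mess you up"
      - "vaccine (killed|is killing|will kill)"
      - "died (right |shortly )?after (getting |taking )?the vaccine"
  - id: conspiracy-claims
    polarity: misinformation
    description: >
      Asserting conspiracy narratives (tracking chips, 5G activation,
      deliberate poisoning, depopulation) as fact.
    indicator_patterns:
      - "vaccines? (contain|have|has) (a )?(microchip|nanobots|tracking)"
      - "5g (activation|antenna in you|chip)"
      - "(plandemic|depopulation agenda)"
  - id: personal-experience
    polarity: non-misinformation
    description: >
      Individuals' own vaccination experience (getting a dose, side effects
      they personally had, relief at being vaccinated).
    indicator_patterns:
      - "(got|received|had) my (first|second|covid) (dose|shot|jab|vaccine)"
      - "just (got|had) (vaccinated|the vaccine|my jab)"
      - "sore arm after (the|my) (shot|jab|vaccine)"
  - id: hopes-and-prayers
    polarity: non-misinformation
    description: >
      Hopes and prayers for the end of the pandemic through vaccines;
      advertisements; general political commentary.
    indicator_patterns:
      - "hope (the )?vaccines? (end|will end|can end) (this|the) pandemic"
      - "praying .* vaccine"
      - "book your vaccination appointment"
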