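format: mcro-card/1
card_id: hiv-social-network
title: Incorporating social network information to predict HIV status
sections:
  - kind: ModelDetails
    heading: Model details
    body: >
      A graph convolutional network that predicts HIV infection status from
      social network survey data among young men who have sex with men.
    annotations:
      description: Overview of the HIV social-network prediction model.
      date: "2022-07-14"
    children:
      - kind: User
        heading: Users
        body: Bioinformatics researchers studying HIV transmission networks.
      - kind: OwnerInformation
        heading: Owners
        body: Academic research group; contact the study team for access.
  - kind: ModelParameters
    heading: Model parameters
    body: Graph neural model over survey-derived social network structure.
    children:
      - kind: ModelArchitecture
        heading: Architecture
        body: Graph convolutional network over the social contact graph.
      - kind: DatasetInformation
        heading: Datasets
        body: Social network survey data with self-reported status labels.
      - kind: FormatInformation
        heading: Format
        body: Edge lists with node-level survey attributes.
  - kind: Considerations
    heading: Considerations
    body: Limits, caveats and impacts on intended users.
    children:
      - kind: TradeOff
        heading: Trade offs
        body: >
          Network-derived features encode sampling bias from the survey
          recruitment process.
      - kind: EthicalConsideration
        heading: Ethical considerations
        body: >
          Status predictions are sensitive; outputs must remain within the
          approved research protocol.
  - kind: QuantitativeAnalysis
    heading: Quantitative analysis
    body: Classification performance across network communities.
    children:
      - kind: PerformanceMetric
        heading: Metrics
        body: Precision, recall and F1 on held-out survey waves.
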