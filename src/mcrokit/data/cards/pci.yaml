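format: mcro-card/1
card_id: pci-adverse-endpoints
title: Adverse endpoints prediction for patients undergoing PCI
sections:
  - kind: ModelDetails
    heading: Model details
    body: >
      A recurrent neural network model for prediction of adverse outcomes
      from coronary artery stent implantation, trained on longitudinal
      electronic health record data.
    annotations:
      description: Overview of the stent adverse-outcome prediction model.
      date: "2022-07-14"
    children:
      - kind: User
        heading: Users
        body: >
          Clinical informatics researchers studying percutaneous coronary
          intervention outcomes.
        annotations:
          source: https://example.org/mcro/pci-card
      - kind: VersionInformation
        heading: Version
        body: Version 1.0 of the model.
      - kind: LicenseInformation
        heading: License
        body: Released for academic research use.
  - kind: ModelParameters
    heading: Model parameters
    body: >
      Sequence model over coded EHR events; inputs are visit sequences and
      outputs are adverse-endpoint risk scores.
    children:
      - kind: ModelArchitecture
        heading: Architecture
        body: Recurrent neural network over temporally ordered encounters.
      - kind: DatasetInformation
        heading: Datasets
        body: De-identified EHR cohort of stent implantation patients.
  - kind: Considerations
    heading: Considerations
    body: Limits, caveats and impacts on intended users.
    children:
      - kind: TradeOff
        heading: Trade offs
        body: >
          Risk scores are calibrated on a single health system and may not
          transfer across institutions.
        annotations:
          note: Also referred to as caveats.
      - kind: EthicalConsideration
        heading: Ethical considerations
        body: >
          Predictions must not be used to deny interventional care.
  - kind: QuantitativeAnalysis
    heading: Quantitative analysis
    body: Discrimination and calibration of the adverse-endpoint predictions.
    children:
      - kind: PerformanceMetric
        heading: Metrics
        body: Area under the receiver operating characteristic curve.
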