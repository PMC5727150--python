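# Bacterial NHEJ system: Ku is mandatory; the LigD ligase is accessory,
# since Ku can recruit other ligases when LigD is absent.  A Ku-only
# cluster therefore counts as a present system.
name: NHEJ
mandatory: [Ku]
accessory: [LigD]
forbidden: []
min_mandatory: 1
colocalization_window: 5
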