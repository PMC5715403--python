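>NifN_ref_synthetic synthetic NifN-like reference template (no biological sequence)
WESERSYSELFCDENYQMHVGQADLAGPGQNWQPCHLPIQIWEPIGRWGSQCHRIIVVGV
CMLEWFHEESVLLQYSKCECTPFVYFIDMRPTEGYAFIERKRWTDTWWFEYPYPGALCDQ
AFVTDFYPENIYPNTMCFVPWWKVSPVKGRGNTNFFQYQV
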