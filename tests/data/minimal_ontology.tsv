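sample_id	tissue	neoplastic
tissue_00+_s000	tissue_00	neoplastic
tissue_00+_s001	tissue_00	neoplastic
tissue_00+_s002	tissue_00	neoplastic
tissue_00+_s003	tissue_00	neoplastic
tissue_00+_s004	tissue_00	neoplastic
tissue_00+_s005	tissue_00	neoplastic
tissue_00+_s006	tissue_00	neoplastic
tissue_00+_s007	tissue_00	neoplastic
tissue_00+_s008	tissue_00	neoplastic
tissue_00+_s009	tissue_00	neoplastic
tissue_00+_s010	tissue_00	neoplastic
tissue_00+_s011	tissue_00	neoplastic
tissue_00-_s000	tissue_00	non-neoplastic
tissue_00-_s001	tissue_00	non-neoplastic
tissue_00-_s002	tissue_00	non-neoplastic
tissue_00-_s003	tissue_00	non-neoplastic
tissue_00-_s004	tissue_00	non-neoplastic
tissue_00-_s005	tissue_00	non-neoplastic
tissue_00-_s006	tissue_00	non-neoplastic
tissue_00-_s007	tissue_00	non-neoplastic
tissue_00-_s008	tissue_00	non-neoplastic
tissue_00-_s009	tissue_00	non-neoplastic
tissue_00-_s010	tissue_00	non-neoplastic
tissue_00-_s011	tissue_00	non-neoplastic
tissue_01+_s000	tissue_01	neoplastic
tissue_01+_s001	tissue_01	neoplastic
tissue_01+_s002	tissue_01	neoplastic
tissue_01+_s003	tissue_01	neoplastic
tissue_01+_s004	tissue_01	neoplastic
tissue_01+_s005	tissue_01	neoplastic
tissue_01+_s006	tissue_01	neoplastic
tissue_01+_s007	tissue_01	neoplastic
tissue_01+_s008	tissue_01	neoplastic
tissue_01+_s009	tissue_01	neoplastic
tissue_01+_s010	tissue_01	neoplastic
tissue_01+_s011	tissue_01	neoplastic
tissue_01-_s000	tissue_01	non-neoplastic
tissue_01-_s001	tissue_01	non-neoplastic
tissue_01-_s002	tissue_01	non-neoplastic
tissue_01-_s003	tissue_01	non-neoplastic
tissue_01-_s004	tissue_01	non-neoplastic
tissue_01-_s005	tissue_01	non-neoplastic
tissue_01-_s006	tissue_01	non-neoplastic
tissue_01-_s007	tissue_01	non-neoplastic
tissue_01-_s008	tissue_01	non-neoplastic
tissue_01-_s009	tissue_01	non-neoplastic
tissue_01-_s010	tissue_01	non-neoplastic
tissue_01-_s011	tissue_01	non-neoplastic
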