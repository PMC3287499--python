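sample_id	class
s001	0
s002	0
s003	0
s004	0
s005	0
s006	0
s007	0
s008	0
s009	0
s010	0
s011	0
s012	0
s013	0
s014	0
s015	0
s016	1
s017	1
s018	1
s019	1
s020	1
s021	1
s022	1
s023	1
s024	1
s025	1
s026	1
s027	1
s028	1
s029	1
s030	1
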