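# reference alignment: A-id<TAB>B-id
http://ontofuse.local/onto#A%3A0000	http://ontofuse.local/onto#B%3A0000
http://ontofuse.local/onto#A%3A0001	http://ontofuse.local/onto#B%3A0001
http://ontofuse.local/onto#A%3A0002	http://ontofuse.local/onto#B%3A0002
http://ontofuse.local/onto#A%3A0003	http://ontofuse.local/onto#B%3A0003
http://ontofuse.local/onto#A%3A0004	http://ontofuse.local/onto#B%3A0004
http://ontofuse.local/onto#A%3A0005	http://ontofuse.local/onto#B%3A0005
http://ontofuse.local/onto#A%3A0006	http://ontofuse.local/onto#B%3A0006
http://ontofuse.local/onto#A%3A0007	http://ontofuse.local/onto#B%3A0007
http://ontofuse.local/onto#A%3A0008	http://ontofuse.local/onto#B%3A0008
http://ontofuse.local/onto#A%3A0009	http://ontofuse.local/onto#B%3A0009
http://ontofuse.local/onto#A%3A0011	http://ontofuse.local/onto#B%3A0011
http://ontofuse.local/onto#A%3A0012	http://ontofuse.local/onto#B%3A0012
http://ontofuse.local/onto#A%3A0013	http://ontofuse.local/onto#B%3A0013
http://ontofuse.local/onto#A%3A0014	http://ontofuse.local/onto#B%3A0014
http://ontofuse.local/onto#A%3A0015	http://ontofuse.local/onto#B%3A0015
http://ontofuse.local/onto#A%3A0016	http://ontofuse.local/onto#B%3A0016
http://ontofuse.local/onto#A%3A0017	http://ontofuse.local/onto#B%3A0017
http://ontofuse.local/onto#A%3A0018	http://ontofuse.local/onto#B%3A0018
http://ontofuse.local/onto#A%3A0019	http://ontofuse.local/onto#B%3A0019
http://ontofuse.local/onto#A%3A0020	http://ontofuse.local/onto#B%3A0020
http://ontofuse.local/onto#A%3A0021	http://ontofuse.local/onto#B%3A0021
http://ontofuse.local/onto#A%3A0022	http://ontofuse.local/onto#B%3A0022
http://ontofuse.local/onto#A%3A0023	http://ontofuse.local/onto#B%3A0023
http://ontofuse.local/onto#A%3A0024	http://ontofuse.local/onto#B%3A0024
http://ontofuse.local/onto#A%3A0025	http://ontofuse.local/onto#B%3A0025
http://ontofuse.local/onto#A%3A0026	http://ontofuse.local/onto#B%3A0026
http://ontofuse.local/onto#A%3A0027	http://ontofuse.local/onto#B%3A0027
http://ontofuse.local/onto#A%3A0028	http://ontofuse.local/onto#B%3A0028
http://ontofuse.local/onto#A%3A0029	http://ontofuse.local/onto#B%3A0029
http://ontofuse.local/onto#A%3A0031	http://ontofuse.local/onto#B%3A0031
http://ontofuse.local/onto#A%3A0032	http://ontofuse.local/onto#B%3A0032
http://ontofuse.local/onto#A%3A0033	http://ontofuse.local/onto#B%3A0033
http://ontofuse.local/onto#A%3A0034	http://ontofuse.local/onto#B%3A0034
http://ontofuse.local/onto#A%3A0035	http://ontofuse.local/onto#B%3A0035
http://ontofuse.local/onto#A%3A0036	http://ontofuse.local/onto#B%3A0036
http://ontofuse.local/onto#A%3A0037	http://ontofuse.local/onto#B%3A0037
http://ontofuse.local/onto#A%3A0038	http://ontofuse.local/onto#B%3A0038
http://ontofuse.local/onto#A%3A0039	http://ontofuse.local/onto#B%3A0039
http://ontofuse.local/onto#A%3A0040	http://ontofuse.local/onto#B%3A0040
http://ontofuse.local/onto#A%3A0041	http://ontofuse.local/onto#B%3A0041
http://ontofuse.local/onto#A%3A0042	http://ontofuse.local/onto#B%3A0042
http://ontofuse.local/onto#A%3A0043	http://ontofuse.local/onto#B%3A0043
http://ontofuse.local/onto#A%3A0044	http://ontofuse.local/onto#B%3A0044
http://ontofuse.local/onto#A%3A0045	http://ontofuse.local/onto#B%3A0045
http://ontofuse.local/onto#A%3A0046	http://ontofuse.local/onto#B%3A0046
http://ontofuse.local/onto#A%3A0047	http://ontofuse.local/onto#B%3A0047
http://ontofuse.local/onto#A%3A0048	http://ontofuse.local/onto#B%3A0048
http://ontofuse.local/onto#A%3A0049	http://ontofuse.local/onto#B%3A0049
http://ontofuse.local/onto#A%3A0050	http://ontofuse.local/onto#B%3A0050
http://ontofuse.local/onto#A%3A0051	http://ontofuse.local/onto#B%3A0051
http://ontofuse.local/onto#A%3A0052	http://ontofuse.local/onto#B%3A0052
http://ontofuse.local/onto#A%3A0053	http://ontofuse.local/onto#B%3A0053
http://ontofuse.local/onto#A%3A0054	http://ontofuse.local/onto#B%3A0054
http://ontofuse.local/onto#A%3A0055	http://ontofuse.local/onto#B%3A0055
http://ontofuse.local/onto#A%3A0056	http://ontofuse.local/onto#B%3A0056
http://ontofuse.local/onto#A%3A0057	http://ontofuse.local/onto#B%3A0057
http://ontofuse.local/onto#A%3A0058	http://ontofuse.local/onto#B%3A0058
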