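DCM001
DCM002
DCM003
DCM004
DCM005
DCM006
DCM007
DCM008
DCM009
DCM010
DCM011
DCM012
DCM013
DCM014
DCM015
DCM016
DCM017
DCM018
DCM019
DCM020
DCM021
DCM022
DCM023
DCM024
DCM025
DCM026
DCM027
DCM028
DCM029
DCM030
DCM031
DCM032
DCM033
DCM034
DCM035
DCM036
DCM037
DCM038
DCM039
DCM040
DCM041
DCM042
DCM043
DCM044
DCM045
DCM046
DCM047
DCM048
DCM049
DCM050
DCM051
DCM052
DCM053
DCM054
DCM055
DCM056
DCM057
DCM058
DCM059
DCM060
DCM061
DCM062
DCM063
DCM064
DCM065
DCM066
DCM067
DCM068
DCM069
DCM070
DCM071
DCM072
DCM073
DCM074
DCM075
DCM076
DCM077
DCM078
DCM079
DCM080
DCM081
DCM082
DCM083
DCM084
DCM085
DCM086
DCM087
DCM088
DCM089
DCM090
DCM091
DCM092
DCM093
DCM094
DCM095
DCM096
DCM097
DCM098
DCM099
DCM100
DCM101
DCM102
DCM103
DCM104
DCM105
DCM106
DCM107
DCM108
DCM109
DCM110
DCM111
DCM112
DCM113
DCM114
DCM115
DCM116
DCM117
DCM118
DCM119
DCM120
DCM121
DCM122
DCM123
DCM124
DCM125
DCM126
DCM127
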