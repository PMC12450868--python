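subject_id,group,sex,affected_side,etiology,dhi,fga_gait_level_surface,fga_change_speed,fga_horizontal_head_turns,fga_vertical_head_turns,fga_turn_pivot,fga_step_obstacle,fga_tandem_walk,fga_eyes_closed,fga_backwards,fga_steps,fga_total
BV01,BV,F,both,ototoxic,48,3,3,3,3,2,1,0,0,2,2,19
BV02,BV,F,both,genetic,46,2,2,3,3,2,3,0,1,2,3,21
BV03,BV,M,both,idiopathic,12,2,3,3,1,3,3,0,1,1,3,20
BV04,BV,F,both,idiopathic,34,2,3,2,2,3,3,0,1,3,2,21
BV05,BV,F,both,idiopathic,20,3,2,2,2,3,3,0,0,2,3,20
BV06,BV,F,both,idiopathic,74,3,3,2,2,2,2,0,1,0,3,18
BV07,BV,M,both,schwannoma,2,3,3,3,3,3,3,0,0,3,3,24
BV08,BV,M,both,idiopathic,40,3,3,3,3,3,3,0,2,3,3,26
BV09,BV,M,both,idiopathic,48,3,3,2,2,2,1,0,0,1,1,15
BV10,BV,F,both,idiopathic,UN,2,3,2,3,3,2,0,2,3,2,22
UV01,UV,F,left,idiopathic,68,1,2,1,2,0,2,2,0,2,2,14
UV02,UV,M,left,idiopathic,6,3,3,3,3,3,3,3,3,3,3,30
UV03,UV,M,left,post-labyrinthectomy,64,2,3,3,3,2,3,2,1,2,1,22
UV04,UV,F,right,idiopathic,14,2,3,3,3,3,3,3,2,3,3,28
UV05,UV,M,left,schwannoma,20,3,3,3,3,3,3,3,2,3,3,29
UV06,UV,M,right,idiopathic,8,3,3,3,3,3,3,2,1,3,3,27
UV07,UV,F,right,idiopathic,2,3,3,3,3,3,3,3,1,3,3,28
UV08,UV,M,right,traumatic,11,3,3,3,3,2,3,3,2,3,3,28
UV09,UV,F,right,schwannoma,52,3,2,3,3,2,2,2,3,3,3,26
UV10,UV,F,right,idiopathic,22,3,3,2,2,3,3,3,2,3,3,27
HS01,HS,F,none,NA,NA,3,3,3,3,3,3,3,2,3,3,29
HS02,HS,F,none,NA,NA,3,3,3,3,3,3,3,3,3,3,30
HS03,HS,M,none,NA,NA,3,3,2,3,3,3,3,2,3,3,28
HS04,HS,M,none,NA,NA,3,3,3,3,3,3,3,3,3,3,30
HS05,HS,F,none,NA,NA,3,3,3,3,3,3,3,3,3,3,30
HS06,HS,F,none,NA,NA,3,3,3,3,3,3,3,3,3,3,30
HS07,HS,M,none,NA,NA,3,3,3,3,3,3,2,3,3,3,29
HS08,HS,F,none,NA,NA,3,3,3,3,3,3,3,2,3,3,29
HS09,HS,M,none,NA,NA,3,3,3,3,3,3,3,2,3,3,29
HS10,HS,M,none,NA,NA,3,3,3,3,3,3,2,2,2,3,27
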